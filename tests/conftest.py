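import numpy as np
import pytest

import phylorda as pr


@pytest.fixture(scope="session")
def fixture_data():
    rows, tree, notes = pr.load_fixture()
    return rows, tree, notes


@pytest.fixture(scope="session")
def fixture_rows(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def fixture_tree(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def response_cov(fixture_rows):
    return pr.build_response_matrix(fixture_rows, scaling="covariance")


@pytest.fixture(scope="session")
def response_cor(fixture_rows):
    return pr.build_response_matrix(fixture_rows, scaling="correlation")


@pytest.fixture(scope="session")
def eco_matrix(fixture_rows):
    return pr.build_ecology_matrix(fixture_rows)


@pytest.fixture(scope="session")
def clade_matrix(fixture_tree):
    return pr.clade_indicators(fixture_tree, min_size=1, labelled_only=True)


def lstsq_fraction(Y, X):
    """Independent oracle: per-column least squares with intercept.

    Explained fraction = sum over response columns of fitted sums of squares
    over total sums of squares, all columns centered first.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    ss_fit = ss_tot = 0.0
    for j in range(Yc.shape[1]):
        beta, *_ = np.linalg.lstsq(Xc, Yc[:, j], rcond=None)
        fit = Xc @ beta
        ss_fit += float(fit @ fit)
        ss_tot += float(Yc[:, j] @ Yc[:, j])
    return ss_fit / ss_tot
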