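import numpy as np
import pytest

from ndfkit.decoders import KinematicsSeries
from ndfkit.lds import SpikeCounts
from ndfkit.synth import make_ground_truth_lds, simulate_reach_session


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def split_session(Y, X, frac=0.7):
    """Train/test split of a paired session at a bin boundary."""
    K = Y.n_bins
    k = int(K * frac)
    Ytr = SpikeCounts(Y.counts[:, :k], Y.bin_width)
    Yte = SpikeCounts(Y.counts[:, k:], Y.bin_width)

    def sub(sl):
        return KinematicsSeries(
            pos=X.pos[:, sl], vel=X.vel[:, sl], bin_width=X.bin_width,
            epoch_labels=None if X.epoch_labels is None else X.epoch_labels[sl],
            trial_ids=None if X.trial_ids is None else X.trial_ids[sl],
            condition_ids=None if X.condition_ids is None else X.condition_ids[sl],
        )

    return Ytr, Yte, sub(slice(None, k)), sub(slice(k, None)), k


@pytest.fixture(scope="session")
def small_session():
    """A 20-trial generator-default session shared across read-only tests."""
    gt = make_ground_truth_lds(d=8, n_channels=24, seed=5)
    Y, X = simulate_reach_session(gt, n_trials=20, seed=5)
    return gt, Y, X
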