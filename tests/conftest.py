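import numpy as np
import pytest

from hypersync import CouplingSpec, generate_dyad, plv, ccorr

FS = 250.0
WIN = 750  # 3 s analysis window in samples
HOP = 125  # 0.5 s hop


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sliding_metric(gt, metric_fn, n_win=WIN, hop=HOP):
    """Metric over sliding windows of the generator's exact analytic signals."""
    vals = []
    for end in range(n_win, len(gt.analytic_a) + 1, hop):
        r = metric_fn(gt.analytic_a[end - n_win:end], gt.analytic_b[end - n_win:end])
        vals.append(r.value)
    return np.asarray(vals)


@pytest.fixture(scope="session")
def noiseless_dyads():
    """Ground truth for one noiseless 120 s dyad per kappa (>= 200 windows)."""
    out = {}
    for kappa in (0.0, 0.5, 1.0, 2.0, 4.0):
        spec = CouplingSpec(
            base_freq=10.0, kappa=kappa, env_corr=0.0, snr=np.inf,
            duration=120.0, fs=FS, seed=42,
        )
        _, _, gt = generate_dyad(spec, with_ground_truth=True)
        out[kappa] = gt
    return out


@pytest.fixture(scope="session")
def mean_plv_by_kappa(noiseless_dyads):
    return {k: float(sliding_metric(gt, plv).mean()) for k, gt in noiseless_dyads.items()}


@pytest.fixture(scope="session")
def null_window_metrics(noiseless_dyads):
    """Per-window PLV and CCorr for the kappa=0 (independent-phase) dyad."""
    gt = noiseless_dyads[0.0]
    return sliding_metric(gt, plv), sliding_metric(gt, ccorr)
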