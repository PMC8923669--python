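import numpy as np
import pytest

from fearpeth.core import SpikeTrain, TrialEvents
from fearpeth.peth import ZScoredPETH
from fearpeth.specs import ProtocolSpec
from fearpeth.synthetic import make_protocol


@pytest.fixture(scope="session")
def default_events() -> TrialEvents:
    """One realisation of the standard delay protocol."""
    return make_protocol(ProtocolSpec(), seed=101)


@pytest.fixture(scope="session")
def short_events() -> TrialEvents:
    """Extinction-only protocol with short ITIs for fast simulations."""
    spec = ProtocolSpec(n_acquisition_trials=0, iti_range_s=(20.0, 30.0))
    return make_protocol(spec, seed=202)


def make_zpeth(
    post_z,
    pre_bins: int = 125,
    bin_width_s: float = 0.04,
    align: str = "tone_onset",
) -> ZScoredPETH:
    """Build a z-scored PETH directly from post-event z values (baseline
    bins are zero), for exercising detection/metric code in isolation."""
    post_z = np.asarray(post_z, dtype=float)
    z = np.concatenate([np.zeros(pre_bins), post_z])
    return ZScoredPETH(
        align=align,
        bin_width_s=bin_width_s,
        window_s=(pre_bins * bin_width_s, post_z.size * bin_width_s),
        z=z,
        baseline_mean=1.0,
        baseline_sd=1.0,
        baseline_window_s=pre_bins * bin_width_s,
        n_trials=14,
        degenerate=False,
    )
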