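import numpy as np
import pytest

from spermage import MethylomeTrack, SiteArray


def make_track(
    pos,
    meth,
    total,
    chrom: str = "chr1",
    sample_id: str = "s",
    tissue: str = "sperm",
) -> MethylomeTrack:
    """Build a one-chromosome track from raw arrays."""
    return MethylomeTrack(
        sample_id, tissue, "", {chrom: SiteArray(pos, meth, total)}
    )


def track_from_beta(pos, beta, coverage: int = 100, **kw) -> MethylomeTrack:
    """Track whose counts encode the given betas exactly (beta * coverage
    must be integral)."""
    pos = np.asarray(pos)
    beta = np.asarray(beta, dtype=float)
    meth = np.rint(beta * coverage).astype(np.int64)
    total = np.full(pos.size, coverage, dtype=np.int64)
    return make_track(pos, meth, total, **kw)


@pytest.fixture
def toy_track():
    return make_track([100, 200, 300], [7, 5, 0], [10, 10, 10])
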