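import numpy as np
import pytest

from replisort import ChannelImage, CountMask, FociBinaryMask, NucleusRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(n_nuc: int, n_rf: int, i_rf: float, label: int = 1,
                frame_id: str = "f0") -> NucleusRecord:
    """Record with the density invariant rho = n_rf / n_nuc maintained."""
    return NucleusRecord(frame_id=frame_id, label=label, n_nuc=n_nuc,
                         n_rf=n_rf, rho_rf=n_rf / n_nuc, i_rf=i_rf)


def disk_mask(shape, centre, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius**2


def brute_force_masked_correlation(a, b, mask, max_lag):
    """Direct nested-loop definition of the masked fluctuation correlation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m = np.asarray(mask, bool)
    mu_a = a[m].mean()
    mu_b = b[m].mean()
    h, w = a.shape
    L = max_lag
    g = np.full((2 * L + 1, 2 * L + 1), np.nan)
    counts = np.zeros((2 * L + 1, 2 * L + 1), dtype=int)
    for xi in range(-L, L + 1):
        for eta in range(-L, L + 1):
            s = 0.0
            n = 0
            for y in range(h):
                for x in range(w):
                    y2, x2 = y + xi, x + eta
                    if 0 <= y2 < h and 0 <= x2 < w and m[y, x] and m[y2, x2]:
                        s += (a[y, x] - mu_a) * (b[y2, x2] - mu_b)
                        n += 1
            counts[xi + L, eta + L] = n
            if n:
                g[xi + L, eta + L] = s / (n * mu_a * mu_b)
    return g, counts
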