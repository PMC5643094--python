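"""Small ordered-alternative test utilities used by the simulation analyses."""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats


def sign_test(x, y, alternative: str = "greater"):
    """Exact paired sign test on x - y, ignoring ties.

    Returns ``(n_positive, n_informative, p)``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0, 0, 1.0
    k = int(np.sum(d > 0))
    p = sstats.binomtest(k, n, 0.5, alternative=alternative).pvalue
    return k, n, float(p)


def page_trend_test(data: np.ndarray):
    """Page's L trend test for an increasing ordered alternative.

    ``data`` is (blocks, treatments): each row is one paired replicate (e.g.
    one seed) measured under the ordered treatments.  Uses the normal
    approximation of L; returns ``(L, z, one_sided_p)``.
    """
    a = np.asarray(data, dtype=float)
    if a.ndim != 2 or a.shape[1] < 3:
        raise ValueError("need a (blocks, >=3 treatments) array")
    b, k = a.shape
    ranks = np.apply_along_axis(sstats.rankdata, 1, a)
    col_rank_sums = ranks.sum(axis=0)
    L = float(np.sum(np.arange(1, k + 1) * col_rank_sums))
    mean_L = b * k * (k + 1) ** 2 / 4.0
    var_L = b * k**2 * (k + 1) * (k**2 - 1) / 144.0
    z = (L - mean_L) / np.sqrt(var_L)
    return L, float(z), float(sstats.norm.sf(z))
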