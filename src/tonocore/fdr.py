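"""False-discovery-rate control shared by voxel selection and group maps.

Two procedures are exposed: the plain Benjamini–Hochberg step-up and the
two-stage adaptive step-up (Benjamini, Krieger & Yekutieli 2006), which
first estimates the number of true nulls from a BH pass at level
q/(1+q) and then reruns BH at a level inflated by m/m0_hat.  When some
hypotheses are clearly false (estimated null fraction < 1) the adaptive
procedure is more powerful than plain BH at the same q.

Both are thin wrappers around :func:`statsmodels.stats.multitest.multipletests`
so that every module in the package uses one implementation.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["fdr_reject"]


def fdr_reject(p: np.ndarray, q: float = 0.05, adaptive: bool = True) -> np.ndarray:
    """Return the boolean rejection vector at FDR level q.

    Parameters
    ----------
    p : array of p-values in [0, 1] (NaN entries are never rejected)
    q : target false-discovery rate
    adaptive : use the two-stage adaptive step-up; False gives plain BH
    """
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    pv = p[valid]
    if pv.size == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    method = "fdr_tsbky" if adaptive else "fdr_bh"
    out[valid] = multipletests(pv, alpha=q, method=method)[0]
    return out
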