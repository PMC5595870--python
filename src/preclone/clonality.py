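"""Cancer cell fraction (CCF) estimation from read counts.

The CCF of a somatic mutation is the fraction of cancer cells in a sample
that carry it.  Given the sample purity ``p``, the local integer copy number
``CN`` and the copy number ``CNt`` of the mutation-bearing allele, the
expected variant allele frequency of a mutation at cancer cell fraction
``CCF`` is

    VAFe = (p * CNt * CCF) / (CN * p + 2 * (1 - p))

where the denominator counts allele copies per cell in the tumor/normal
mixture (normal cells contribute 2 copies; sex chromosomes are excluded
upstream).  The observed alt/total read counts (A, N) are scored against a
grid of 100 candidate CCF values 0.01, 0.02, ..., 1.00 with the binomial
likelihood

    P(CCF) = Binom(A | N, VAFe(CCF))

normalized over the grid (flat prior).  The maximum a posteriori value is
the point estimate; a mutation with MAP CCF < 0.8 is subclonal, and ties in
the posterior are broken toward the larger CCF (favoring clonal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import binom

__all__ = [
    "CcfInput",
    "CcfEstimate",
    "ccf_grid",
    "expected_vaf",
    "ccf_posterior",
    "choose_cnt",
    "compare_ccf_pair",
]


@dataclass(frozen=True)
class CcfInput:
    """Read counts and sample context for one mutation in one sample."""

    a: int          # alt read count
    n: int          # total depth at the site
    p: float        # sample purity in (0, 1]
    cn: int         # local total integer copy number, >= 1
    cnt: int        # copy number of the mutation-bearing allele, 1..cn

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n):
            raise ValueError(f"require 0 <= A <= N, got A={self.a}, N={self.n}")
        if not (0 < self.p <= 1):
            raise ValueError(f"purity must be in (0, 1], got {self.p}")
        if self.cn < 1:
            raise ValueError(f"CN must be >= 1, got {self.cn}")
        if not (1 <= self.cnt <= self.cn):
            raise ValueError(f"require 1 <= CNt <= CN, got CNt={self.cnt}, CN={self.cn}")


@dataclass
class CcfEstimate:
    grid: np.ndarray            # the 100 candidate CCF values
    posterior: np.ndarray       # normalized probability per grid value
    map_ccf: float
    clonal: bool
    vafe_map: float             # expected VAF at the MAP CCF
    vafo: float                 # observed VAF A/N


def ccf_grid(size: int = 100) -> np.ndarray:
    """Candidate CCF values 1/size, 2/size, ..., 1 (default 0.01..1.00)."""
    return np.arange(1, size + 1) / size


def expected_vaf(p: float, cn: int, cnt: int, ccf) -> np.ndarray | float:
    """Expected VAF of a mutation at cancer cell fraction ``ccf``.

    ``ccf`` may be a scalar or array; values must lie in (0, 1].  The
    matched normal contributes 2 copies per cell.
    """
    if not (0 < p <= 1):
        raise ValueError(f"purity must be in (0, 1], got {p}")
    if cn < 1:
        raise ValueError(f"CN must be >= 1, got {cn}")
    if not (1 <= cnt <= cn):
        raise ValueError(f"require 1 <= CNt <= CN, got CNt={cnt}, CN={cn}")
    c = np.asarray(ccf, dtype=float)
    if np.any((c <= 0) | (c > 1)):
        raise ValueError("CCF values must lie in (0, 1]")
    out = p * cnt * c / (cn * p + 2.0 * (1.0 - p))
    return float(out) if np.isscalar(ccf) else out


def ccf_posterior(
    inp: CcfInput,
    grid_size: int = 100,
    clonal_cutoff: float = 0.8,
) -> CcfEstimate:
    """Grid posterior over CCF and the MAP clonality call.

    Scores the binomial mass of (A, N) at VAFe(ccf) for each grid value,
    normalizes (flat prior), and returns the argmax with ties broken toward
    the larger CCF.  ``N == 0`` carries no evidence and raises.
    """
    if inp.n == 0:
        raise ValueError("N = 0: no read evidence at this site")
    grid = ccf_grid(grid_size)
    vafe = np.clip(expected_vaf(inp.p, inp.cn, inp.cnt, grid), 1e-12, 1 - 1e-12)
    logp = binom.logpmf(inp.a, inp.n, vafe)
    logp -= logp.max()
    post = np.exp(logp)
    post /= post.sum()
    # ties -> larger CCF (favors the clonal call)
    best = np.flatnonzero(post == post.max())[-1]
    map_ccf = float(grid[best])
    return CcfEstimate(
        grid=grid,
        posterior=post,
        map_ccf=map_ccf,
        clonal=map_ccf >= clonal_cutoff,
        vafe_map=float(expected_vaf(inp.p, inp.cn, inp.cnt, map_ccf)),
        vafo=inp.a / inp.n,
    )


def choose_cnt(
    a: int,
    n: int,
    p: float,
    cn: int,
    major: int,
    minor: int,
    grid_size: int = 100,
) -> tuple[int, dict[int, float]]:
    """Pick the mutant-allele copy number (major or minor CN).

    Fits the grid posterior once with CNt = major and once with CNt = minor
    and keeps the choice with the larger best-grid likelihood; ties prefer
    the major allele.  Returns (cnt, {candidate: best log-likelihood}).
    """
    if major < minor:
        raise ValueError("major CN must be >= minor CN")
    grid = ccf_grid(grid_size)
    fits: dict[int, float] = {}
    for cand in {major, max(minor, 1)}:
        vafe = np.clip(expected_vaf(p, cn, cand, grid), 1e-12, 1 - 1e-12)
        fits[cand] = float(binom.logpmf(a, n, vafe).max())
    best = max(sorted(fits, reverse=True), key=lambda c: (fits[c], c))
    return best, fits


def compare_ccf_pair(
    ccf_x: dict[str, float],
    ccf_y: dict[str, float],
    clonal_cutoff: float = 0.8,
    bin_width: float = 0.05,
    min_count: int = 1,
) -> pd.DataFrame:
    """Place shared mutations on the (CCF_x, CCF_y) plane and cluster them.

    Clustering is a 2-D histogram at ``bin_width`` resolution whose occupied
    cells (count >= min_count) are merged into connected components; each
    mutation is labeled with its component id plus a clonality quadrant
    (clonal-both / clonal-x-only / clonal-y-only / subclonal-both).  This is
    the comparison used to argue lineage direction between two regions: a
    cluster clonal in one sample but subclonal in the other indicates the
    first derived from a subclone of the second.
    """
    shared = sorted(set(ccf_x) & set(ccf_y))
    if not shared:
        raise ValueError("no shared mutations between the two samples")
    x = np.array([ccf_x[m] for m in shared])
    y = np.array([ccf_y[m] for m in shared])
    nbins = int(round(1.0 / bin_width))
    ix = np.minimum((x / bin_width).astype(int), nbins - 1)
    iy = np.minimum((y / bin_width).astype(int), nbins - 1)
    hist = np.zeros((nbins, nbins), dtype=int)
    np.add.at(hist, (ix, iy), 1)
    labels, _ = ndimage.label(hist >= min_count)
    quadrant = np.where(
        x >= clonal_cutoff,
        np.where(y >= clonal_cutoff, "clonal-both", "clonal-x-only"),
        np.where(y >= clonal_cutoff, "clonal-y-only", "subclonal-both"),
    )
    return pd.DataFrame(
        {
            "mutation": shared,
            "ccf_x": x,
            "ccf_y": y,
            "cluster": labels[ix, iy],
            "label": quadrant,
        }
    )
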