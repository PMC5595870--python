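"""96-channel trinucleotide mutation spectra and signature refitting.

Single-base substitutions are reduced to 6 pyrimidine-centric classes
(C>A, C>G, C>T, T>A, T>C, T>G); with the 5' and 3' flanking bases this
gives 96 substitution types.  Mutations reported on the purine strand are
reverse-complemented into the pyrimidine representation, so a spectrum is
invariant to the strand on which the input records a variant.

Per-sample spectra are decomposed against a fixed reference signature set by
forward-selection non-negative least squares: signatures are added one at a
time, each step keeping the signature that most reduces the squared
reconstruction error; signatures ending with weight below 0.06 are dropped
and the remainder renormalized.  Samples with fewer than 50 SNVs are
excluded from decomposition (too little data for a stable refit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical channel order: substitution class major, flanks lexicographic
CHANNELS_96 = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in BASES for f3 in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, flank5: str, flank3: str) -> str:
    """Map a substitution with flanks to its pyrimidine-centric channel."""
    if ref in ("G", "A"):
        ref, alt = _COMP[ref], _COMP[alt]
        flank5, flank3 = _COMP[flank3], _COMP[flank5]
    return f"{flank5}[{ref}>{alt}]{flank3}"


def parse_channel(channel: str) -> tuple[str, str, str, str]:
    """Inverse of :func:`channel_of`: returns (ref, alt, flank5, flank3)."""
    f5, rest = channel[0], channel[2:-2]
    ref, alt = rest.split(">")
    return ref, alt, f5, channel[-1]


@dataclass
class Spectrum96:
    counts: pd.Series           # indexed by CHANNELS_96
    fractions: pd.Series | None  # None when the spectrum is empty
    n_snvs: int
    n_skipped: int              # non-SNV records dropped


@dataclass
class SignatureWeights:
    weights: pd.Series          # per-reference weight, >= 0, sums to 1 (or empty)
    residual: float             # 2-norm of (spectrum - reconstruction)
    n_snvs: int
    excluded: bool              # True when n_snvs < the minimum


def spectrum(mutations: pd.DataFrame) -> Spectrum96:
    """Tabulate the 96-channel spectrum of a mutation table.

    Expects columns ``ref`` and ``alt`` plus either a 3-mer ``context``
    column (reference strand, mutated base in the middle) or ``flank5`` /
    ``flank3`` columns.  Records that are not single-base substitutions are
    skipped and counted.
    """
    counts = np.zeros(96, dtype=int)
    skipped = 0
    has_ctx = "context" in mutations.columns
    for row in mutations.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _COMP or alt not in _COMP or ref == alt:
            skipped += 1
            continue
        if has_ctx:
            ctx = str(row.context).upper()
            if len(ctx) != 3 or ctx[1] != ref:
                skipped += 1
                continue
            f5, f3 = ctx[0], ctx[2]
        else:
            f5, f3 = str(row.flank5).upper(), str(row.flank3).upper()
        counts[_CHANNEL_INDEX[channel_of(ref, alt, f5, f3)]] += 1
    total = int(counts.sum())
    s = pd.Series(counts, index=list(CHANNELS_96))
    fr = s / total if total > 0 else None
    return Spectrum96(counts=s, fractions=fr, n_snvs=total, n_skipped=skipped)


def reference_signatures(n_signatures: int = 30) -> pd.DataFrame:
    """Synthetic stand-in reference signature set (30 x 96).

    These profiles are generated deterministically in code and are NOT the
    COSMIC catalog: they are synthetic stand-ins playing the same role
    (a fixed reference basis for refitting).  Signature.1 models the
    spontaneous-deamination process that dominates these tumors -- C>T
    transitions concentrated at NpCpG contexts; the remaining profiles are
    sparse random spectra, mutually near-orthogonal so that mixture
    recovery is well-posed.
    """
    rng = np.random.Generator(np.random.PCG64(20170301))
    profiles = np.empty((n_signatures, 96))
    # Signature.1: 75% of mass on the four N[C>T]G channels, rest uniform.
    sig1 = np.full(96, 0.25 / 96)
    cpg = [_CHANNEL_INDEX[f"{f5}[C>T]G"] for f5 in BASES]
    sig1[cpg] += 0.75 / 4
    profiles[0] = sig1
    for i in range(1, n_signatures):
        profiles[i] = rng.dirichlet(np.full(96, 0.08))
    profiles /= profiles.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        profiles,
        index=[f"Signature.{i + 1}" for i in range(n_signatures)],
        columns=list(CHANNELS_96),
    )


def decompose(
    spec: Spectrum96,
    references: pd.DataFrame | None = None,
    min_snvs: int = 50,
    min_weight: float = 0.06,
    tol: float = 1e-6,
) -> SignatureWeights:
    """Refit a spectrum against the reference signatures.

    Forward selection: starting from the empty model, repeatedly add the
    reference whose inclusion (with a full NNLS refit of the selected set)
    most reduces the squared reconstruction error, stopping when the
    improvement falls below ``tol``.  Weights below ``min_weight`` after
    selection are dropped, the kept set refit and renormalized to sum to 1.
    """
    if references is None:
        references = reference_signatures()
    R = references.to_numpy()
    if R.shape[1] != 96:
        raise ValueError("reference matrix must have 96 channels per signature")
    if spec.n_snvs < min_snvs:
        return SignatureWeights(
            weights=pd.Series(dtype=float),
            residual=float("nan"),
            n_snvs=spec.n_snvs,
            excluded=True,
        )
    f = spec.fractions.to_numpy()
    selected: list[int] = []
    best_w = np.zeros(0)
    err = float(f @ f)
    while len(selected) < len(R):
        cand_err, cand_j, cand_w = None, None, None
        for j in range(len(R)):
            if j in selected:
                continue
            w, rnorm = nnls(R[selected + [j]].T, f)
            if cand_err is None or rnorm**2 < cand_err:
                cand_err, cand_j, cand_w = rnorm**2, j, w
        if cand_err is None or err - cand_err < tol:
            break
        selected.append(cand_j)
        best_w, err = cand_w, cand_err
    names = references.index[selected]
    weights = pd.Series(best_w, index=names)
    total = weights.sum()
    if total > 0:
        keep = weights / total >= min_weight
        weights = weights[keep]
    if len(weights) == 0:
        return SignatureWeights(
            weights=pd.Series(dtype=float),
            residual=float(np.linalg.norm(f)),
            n_snvs=spec.n_snvs,
            excluded=False,
        )
    kept_idx = [references.index.get_loc(n) for n in weights.index]
    w, _ = nnls(R[kept_idx].T, f)
    if w.sum() > 0:
        w = w / w.sum()
    residual = float(np.linalg.norm(f - R[kept_idx].T @ w))
    return SignatureWeights(
        weights=pd.Series(w, index=weights.index),
        residual=residual,
        n_snvs=spec.n_snvs,
        excluded=False,
    )


def sample_contexts(
    n: int,
    signature_weights: dict[str, float] | pd.Series,
    references: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str]]:
    """Draw (ref, alt, context) triplets from a signature mixture.

    Used by the synthetic generator.  Half the draws are emitted on the
    purine strand so that downstream spectra exercise the strand-collapse
    rule.
    """
    if references is None:
        references = reference_signatures()
    if rng is None:
        rng = np.random.default_rng()
    wv = pd.Series(signature_weights, dtype=float).reindex(references.index).fillna(0.0)
    if wv.sum() <= 0:
        raise ValueError("signature mixture weights must have positive sum")
    probs = (wv / wv.sum()).to_numpy() @ references.to_numpy()
    probs = probs / probs.sum()
    idx = rng.choice(96, size=n, p=probs)
    flip = rng.random(n) < 0.5
    out = []
    for k, do_flip in zip(idx, flip):
        ref, alt, f5, f3 = parse_channel(CHANNELS_96[k])
        ctx = f5 + ref + f3
        if do_flip:
            ref, alt, ctx = _COMP[ref], _COMP[alt], revcomp(ctx)
        out.append((ref, alt, ctx))
    return out
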