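"""Position-weight-matrix scoring of allele effects on TF binding.

Scores are additive over positions and min-max scaled to the motif's
attainable score range, so every scaled score lies in [0, 1] and the
consensus sequence scores exactly 1. The effect of a SNP on a motif is
|scoreRef - scoreAlt| over the best-scoring window (both strands, all
windows overlapping the SNP), itself a fraction of the scoring range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PWM", "AlleleMotifScore", "pwm_allele_scores", "load_jaspar", "load_meme"]

_ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PWM:
    """A motif's per-position base weights (rows = positions, cols = ACGT)."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4)

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (L, 4) with L >= 1")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def score_min(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    @property
    def score_max(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1])

    def scaled_score(self, window: str) -> float:
        """Min-max scaled additive score of one length-L window."""
        if len(window) != self.length:
            raise ValueError("window length must equal motif length")
        idx = [_INDEX[b] for b in window]  # KeyError on ambiguous bases
        raw = float(self.matrix[np.arange(self.length), idx].sum())
        rng = self.score_max - self.score_min
        if rng == 0.0:
            return 0.0  # constant matrix: degenerate, all sequences equivalent
        return (raw - self.score_min) / rng


@dataclass(frozen=True)
class AlleleMotifScore:
    site_id: str
    tf_id: str
    score_ref: float
    score_alt: float

    @property
    def effect(self) -> float:
        return abs(self.score_ref - self.score_alt)


def _best_scaled(pwm: PWM, seq: str, snp_offset: int, aggregate: str = "max") -> float | None:
    """Best scaled score over windows overlapping the SNP, both strands.

    Windows containing ambiguous bases are skipped; returns None when
    every window is skipped.
    """
    L = pwm.length
    rc = seq.translate(_COMPLEMENT)[::-1]
    rc_offset = len(seq) - 1 - snp_offset
    scores: list[float] = []
    for s, off in ((seq, snp_offset), (rc, rc_offset)):
        lo = max(0, off - L + 1)
        hi = min(len(s) - L, off)
        for w in range(lo, hi + 1):
            try:
                scores.append(pwm.scaled_score(s[w : w + L]))
            except KeyError:
                continue
    if not scores:
        return None
    if aggregate == "max":
        return max(scores)
    if aggregate == "mean":
        return float(np.mean(scores))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def pwm_allele_scores(
    pwm: PWM,
    context: str,
    snp_offset: int,
    ref: str,
    alt: str,
    site_id: str = "",
    aggregate: str = "max",
) -> AlleleMotifScore:
    """Score both alleles of a SNP in its sequence context against a motif.

    ``context`` is the genomic sequence around the SNP; ``snp_offset`` is
    the 0-based position of the SNP within it. The base at the offset is
    substituted by each allele before scanning. Raises ValueError when
    the context is shorter than the motif or all windows are ambiguous.
    """
    context = context.upper()
    if len(context) < pwm.length:
        raise ValueError("context shorter than motif")
    if not 0 <= snp_offset < len(context):
        raise ValueError("snp_offset outside context")
    out = {}
    for name, allele in (("ref", ref.upper()), ("alt", alt.upper())):
        seq = context[:snp_offset] + allele + context[snp_offset + 1 :]
        s = _best_scaled(pwm, seq, snp_offset, aggregate)
        if s is None:
            raise ValueError("all windows contain ambiguous bases")
        out[name] = s
    return AlleleMotifScore(site_id, pwm.motif_id, out["ref"], out["alt"])


# -- motif file parsing (JASPAR pfm / MEME minimal, via Bio.motifs) ------


def _from_biomotif(motif, motif_id: str) -> PWM:
    counts = np.array([motif.counts[b] for b in _ALPHABET], float).T  # (L, 4)
    col_sums = counts.sum(axis=1, keepdims=True)
    col_sums[col_sums == 0] = 1.0
    return PWM(motif_id, counts / col_sums)


def load_jaspar(path: str | Path) -> list[PWM]:
    """Load JASPAR-format motifs as frequency PWMs."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    return [
        _from_biomotif(m, m.matrix_id or m.name or f"motif{k}")
        for k, m in enumerate(parsed)
    ]


def load_meme(path: str | Path) -> list[PWM]:
    """Load MEME minimal-format motifs as frequency PWMs."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "minimal")
    return [
        _from_biomotif(m, m.name or f"motif{k}") for k, m in enumerate(parsed)
    ]
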