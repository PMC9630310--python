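"""Closed-form on/off-target scoring.

Off-target likelihoods: the CFD score is a product of experimentally derived
position- and base-specific mismatch tolerance weights w_p(x_RNA, x_DNA)
over the mismatched positions; the MIT score combines per-position weights
c_p with the mean pairwise distance d between mismatches and the mismatch
count m:

    MIT = (prod c_p) * 1 / (((L - d) / L) * 4 + 1) * 1 / m**2

Guide-level specificity aggregates per-off-target cutting likelihoods C_i by
inverse summation, 1 / (1 + sum C_i): a guide with no off-targets scores 1,
one with a second perfect-complementarity locus scores 0.5.

On-target composites are rank averages across scoring methods, with ranks
rescaled so the best rank is comparable when methods differ in missingness.

The CFD-CasRx procedure estimates position-wise mismatch tolerance weights
for an RNA-targeting nuclease from a single-mismatch (SM) tiling screen:
LOESS-smooth the LFC difference between each SM guide and its perfect-match
(PM) parent against spacer position, then express the fitted values as
relative activity against the PM median LFC, clamped to [0, 1].
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .offtargets import AlignmentHit

NUCLEOTIDES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Weight tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MismatchWeightTable:
    """CFD-style mismatch tolerance weights w_p(x_RNA, x_DNA).

    Positions run 1..L from the PAM-distal end of the protospacer.
    Perfect-match entries are implicitly 1. ``pam_weights``, when present,
    multiply the score by a PAM-dependent tolerance factor.
    """

    w: Mapping[tuple[int, str, str], float]
    L: int
    pam_weights: Mapping[str, float] | None = None

    def weight(self, p: int, rna: str, dna: str) -> float:
        if rna == dna:
            return 1.0
        try:
            return self.w[(p, rna, dna)]
        except KeyError:
            raise KeyError(
                f"no mismatch weight for (p={p}, RNA={rna}, DNA={dna})"
            ) from None

    @classmethod
    def from_position_weights(cls, weights: Mapping[int, float], L: int | None = None):
        """Base-agnostic table (e.g. CFD-CasRx) from position->weight."""
        L = L if L is not None else max(weights)
        w = {
            (p, a, b): float(weights[p])
            for p in weights
            for a in NUCLEOTIDES
            for b in NUCLEOTIDES
            if a != b
        }
        return cls(w=w, L=L)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pam_weights=None):
        w = {
            (int(r.position), str(r.ref_base).upper(), str(r.alt_base).upper()):
                float(r.weight)
            for r in df.itertuples()
        }
        return cls(w=w, L=max(p for p, _, _ in w), pam_weights=pam_weights)

    @classmethod
    def from_tsv(cls, path: str | Path):
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def from_json(cls, path: str | Path):
        with open(path) as fh:
            doc = json.load(fh)
        w = {
            (int(r["position"]), str(r["ref_base"]).upper(),
             str(r["alt_base"]).upper()): float(r["weight"])
            for r in doc["weights"]
        }
        return cls(
            w=w,
            L=int(doc.get("spacer_length", max(p for p, _, _ in w))),
            pam_weights=doc.get("pam_weights"),
        )


@dataclass(frozen=True)
class MitWeights:
    """MIT per-position mismatch tolerance weights c_p, p in 1..L."""

    c: Mapping[int, float]
    L: int = 19

    def weight(self, p: int) -> float:
        try:
            return self.c[p]
        except KeyError:
            raise KeyError(f"no MIT weight for position {p}") from None

    @classmethod
    def from_tsv(cls, path: str | Path):
        df = pd.read_csv(path, sep="\t", comment="#")
        c = {int(r.position): float(r.weight) for r in df.itertuples()}
        return cls(c=c, L=max(c))


# ---------------------------------------------------------------------------
# Per-hit scores
# ---------------------------------------------------------------------------


def cfd_score(hit: AlignmentHit, weights: MismatchWeightTable) -> float:
    """Cutting frequency determination score of one (off-)target hit.

    Product of the mismatch tolerance weights over the hit's mismatched
    positions (1.0 for a perfect match), optionally multiplied by a
    PAM-dependent factor when the table carries PAM weights.
    """
    score = 1.0
    for p, rna, dna in hit.mismatch_positions:
        if p > weights.L:
            raise ValueError(
                f"mismatch position {p} beyond weight table length {weights.L}"
            )
        score *= weights.weight(p, rna, dna)
    if weights.pam_weights is not None:
        try:
            score *= weights.pam_weights[hit.pam_observed]
        except KeyError:
            raise KeyError(
                f"no PAM weight for observed PAM {hit.pam_observed!r}"
            ) from None
    return score


def mit_score(hit: AlignmentHit, weights: MitWeights) -> float:
    """MIT off-target cutting likelihood of one hit.

    Perfect matches score 1.0 by convention. With a single mismatch the
    pairwise-distance term is undefined and the distance factor is set to 1
    (equivalently d = L), leaving the per-position weight alone.
    """
    m = hit.n_mismatches
    if m == 0:
        return 1.0
    positions = [p for p, _, _ in hit.mismatch_positions]
    for p in positions:
        if p > weights.L:
            raise ValueError(
                f"mismatch position {p} beyond weight table length {weights.L}"
            )
    prod = math.prod(weights.weight(p) for p in positions)
    if m == 1:
        d = float(weights.L)
    else:
        d = float(np.mean([abs(a - b) for a, b in itertools.combinations(positions, 2)]))
    distance_factor = 1.0 / (((weights.L - d) / weights.L) * 4.0 + 1.0)
    return prod * distance_factor / (m * m)


def specificity_score(offtarget_cutting_scores: Iterable[float]) -> float:
    """Guide-level specificity 1 / (1 + sum of off-target cutting scores).

    The list covers every putative off-target except the guide's primary
    on-target; additional perfect-complementarity loci enter with score 1.
    """
    total = 0.0
    for c in offtarget_cutting_scores:
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"cutting score outside [0, 1]: {c}")
        total += c
    return 1.0 / (1.0 + total)


def score_hits(
    hits: list[AlignmentHit],
    weights: MismatchWeightTable | None = None,
    mit_weights: MitWeights | None = None,
) -> pd.DataFrame:
    """Per-hit score table (one row per hit, CFD and/or MIT columns)."""
    rows = []
    for h in hits:
        row = {
            "guide_id": h.guide_id,
            "subject_id": h.subject_id,
            "pam_coordinate": h.pam_coordinate,
            "strand": h.strand,
            "n_mismatches": h.n_mismatches,
            "is_on_target": h.is_on_target,
        }
        if weights is not None:
            row["score_cfd"] = cfd_score(h, weights)
        if mit_weights is not None:
            row["score_mit"] = mit_score(h, mit_weights)
        rows.append(row)
    return pd.DataFrame(rows)


def guide_specificity(
    hits: list[AlignmentHit],
    weights: MismatchWeightTable,
    guide_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Aggregate per-hit CFD scores into per-guide specificity.

    For each guide the primary on-target hit is excluded; every other hit —
    including additional perfect matches, which score 1 — contributes its
    CFD cutting likelihood to the inverse sum.
    """
    per_guide: dict[str, list[float]] = {g: [] for g in (guide_ids or [])}
    for h in hits:
        per_guide.setdefault(h.guide_id, [])
        if not h.is_on_target:
            per_guide[h.guide_id].append(cfd_score(h, weights))
    return pd.Series(
        {g: specificity_score(cs) for g, cs in per_guide.items()}
    ).sort_index()


# ---------------------------------------------------------------------------
# Composite on-target score
# ---------------------------------------------------------------------------


def composite_on_target(
    scores: pd.DataFrame, methods: Sequence[str] | None = None
) -> pd.Series:
    """Rank-average composite of several on-target scoring methods.

    Within each method, guides are ranked ascending so the best (largest)
    raw score gets the largest rank; ties receive the average rank; guides
    missing from a method are excluded from that method's ranking. Because
    the number of non-missing values may differ across methods, each
    method's ranks are rescaled so its maximum rank equals the global
    maximum, keeping the scales comparable. The composite is the mean of a
    guide's rescaled ranks over the methods scoring it; larger is better.
    """
    methods = list(methods) if methods is not None else list(scores.columns)
    if not methods:
        raise ValueError("at least one score column is required")
    usable = []
    for m in methods:
        if m not in scores.columns:
            raise ValueError(f"score column {m!r} not present")
        if scores[m].notna().sum() == 0:
            warnings.warn(f"score column {m!r} is all-missing; dropped", stacklevel=2)
        else:
            usable.append(m)
    if not usable:
        raise ValueError("all requested score columns are entirely missing")
    max_rank = max(scores[m].notna().sum() for m in usable)
    ranked = {}
    for m in usable:
        r = scores[m].rank(method="average", na_option="keep")
        n = scores[m].notna().sum()
        ranked[m] = r * (max_rank / n)
    return pd.DataFrame(ranked).mean(axis=1, skipna=True)


def frameshift_proportion(indel_distribution: Mapping[int, float]) -> float:
    """Probability mass on indel lengths not divisible by 3.

    Under a uniform distribution of indel lengths this is 2/3 — the chance
    level against which frameshift-predictive scores are read.
    """
    if 0 in indel_distribution:
        raise ValueError("indel length 0 is not an indel")
    total = math.fsum(indel_distribution.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"indel probabilities sum to {total}, expected 1")
    return math.fsum(
        p for length, p in indel_distribution.items() if length % 3 != 0
    )


# ---------------------------------------------------------------------------
# CFD-CasRx: mismatch weights from a single-mismatch tiling screen
# ---------------------------------------------------------------------------


def estimate_casrx_mismatch_weights(
    sm_table: pd.DataFrame,
    pm_median_lfc: float,
    loess_span: float = 0.25,
    positions: Sequence[int] | None = None,
) -> dict[int, float]:
    """Position-wise mismatch tolerance weights from SM-vs-PM LFC losses.

    ``sm_table`` carries one row per single-mismatch guide with columns
    ``position`` (spacer position of the mismatch, 1-based) and
    ``delta_lfc`` (LFC_SM - LFC_PM of its perfect-match parent). A LOESS
    curve of delta-LFC against position is evaluated at each spacer
    position, and the fitted loss is converted to relative activity against
    the PM median LFC:

        weight(p) = clamp((pm_median_lfc + fit(p)) / pm_median_lfc, 0, 1)

    The sign convention is that of an enrichment (FACS) screen: positive
    LFC means activity, so a fitted delta of 0 gives weight 1 and a fitted
    delta of -pm_median_lfc gives weight 0.
    """
    if pm_median_lfc <= 0:
        raise ValueError("pm_median_lfc must be positive (enrichment convention)")
    pos = np.asarray(sm_table["position"], dtype=float)
    delta = np.asarray(sm_table["delta_lfc"], dtype=float)
    ok = np.isfinite(pos) & np.isfinite(delta)
    if not ok.all():
        warnings.warn(
            f"dropped {int((~ok).sum())} non-finite delta-LFC rows", stacklevel=2
        )
        pos, delta = pos[ok], delta[ok]
    if len(np.unique(pos)) < 2:
        raise ValueError("need >= 2 distinct mismatch positions")
    if positions is None:
        positions = range(int(pos.min()), int(pos.max()) + 1)
    xvals = np.asarray(sorted(positions), dtype=float)
    fitted = lowess(delta, pos, frac=loess_span, xvals=xvals)
    weights = np.clip((pm_median_lfc + fitted) / pm_median_lfc, 0.0, 1.0)
    return {int(p): float(w) for p, w in zip(xvals, weights)}


def predict_mismatch_lfc(
    pm_lfc: float,
    weights: Mapping[int, float],
    mismatch_positions: Iterable[int],
) -> float:
    """Predicted LFC of a mismatched guide from its perfect-match parent.

    The PM guide's LFC is multiplied by the mismatch tolerance weight at
    each mismatched position (the CFD-CasRx on-target score).
    """
    score = 1.0
    for p in mismatch_positions:
        try:
            score *= weights[p]
        except KeyError:
            raise KeyError(f"no mismatch weight for position {p}") from None
    return pm_lfc * score
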