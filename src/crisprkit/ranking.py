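"""Default multi-round guide rankings.

Guides are binned into rounds of decreasing priority from their off-target
profile, then overridden into a last round by disqualifying sequence
features, and finally ordered within rounds by positional and activity
criteria. For Cas9-class nucleases:

  round 1: unique target (exactly one 0-mismatch alignment) and no 1-2
           mismatch off-targets in coding regions;
  round 2: fewer than 5 one- or two-mismatch off-targets;
  round 3: everything else;
  round 4: overrides — SNP overlap, a TTTT stretch, or GC content outside
           20-80%.

Within a round, guides cutting within the first 85% of the canonical CDS
are prioritised, then guides in conserved regions (conservation score
> 0), then the composite on-target activity rank.

For CasRx (RNA-targeting), rounds 1/2 require targeting at least 75%/50%
of a gene's isoforms with no 1-2 mismatch off-targets, round 4 overrides
are polyT or extreme GC, and within-round order follows the supplied
on-target score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .guides import GuideSet
from .scoring import composite_on_target


@dataclass(frozen=True)
class RankingParams:
    max_mm_offtargets: int = 5
    gc_bounds: tuple[float, float] = (0.20, 0.80)
    cds_cutoff_pct: float = 85.0
    conservation_sign_cutoff: float = 0.0
    isoform_thresholds: tuple[float, float] = (0.75, 0.50)
    score_columns: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0 <= self.gc_bounds[0] < self.gc_bounds[1] <= 1):
            raise ValueError("gc_bounds must satisfy 0 <= low < high <= 1")
        if self.max_mm_offtargets < 1:
            raise ValueError("max_mm_offtargets must be >= 1")
        r1, r2 = self.isoform_thresholds
        if not (0 < r2 <= r1 <= 1):
            raise ValueError("isoform_thresholds must satisfy 0 < round2 <= round1 <= 1")


def _require(guide, keys: Sequence[str]):
    for k in keys:
        if k not in guide.annotations:
            raise ValueError(
                f"guide {guide.id} lacks required annotation {k!r}; "
                "run the corresponding annotation step first"
            )


def _num(value, default=None):
    if value is None:
        return default
    if isinstance(value, float) and math.isnan(value):
        return default
    return value


def _finalise(guides: GuideSet, order_key) -> pd.DataFrame:
    """Assign within-round and overall ranks from a per-guide sort key."""
    ordered = sorted(guides, key=order_key)
    within: dict[int, int] = {}
    for overall, g in enumerate(ordered, start=1):
        rnd = g.annotations["round"]
        within[rnd] = within.get(rnd, 0) + 1
        g.annotations["within_round_rank"] = within[rnd]
        g.annotations["overall_rank"] = overall
    df = guides.to_frame()
    return df.sort_values("overall_rank").reset_index(drop=True)


def _composite_scores(guides: GuideSet, params: RankingParams) -> dict[str, float]:
    """Composite on-target rank per guide, with fallbacks.

    Uses the configured score columns when any are annotated; otherwise
    falls back to the specificity score; otherwise every guide ties and
    order falls through to the guide id.
    """
    df = guides.to_frame().set_index("id")
    cols = [c for c in params.score_columns if c in df.columns and df[c].notna().any()]
    if cols:
        comp = composite_on_target(df[cols], cols)
        return comp.to_dict()
    if "specificity" in df.columns and df["specificity"].notna().any():
        return df["specificity"].fillna(0.0).to_dict()
    return {g.id: 0.0 for g in guides}


def rank_guides_cas9(
    guides: GuideSet, params: RankingParams = RankingParams()
) -> pd.DataFrame:
    """Multi-round ranking for DNA-cutting Cas9-class nucleases.

    Requires per-guide alignment summaries (``n0``,
    ``n_mm12_offtargets``, ``n_mm12_coding_offtargets``), sequence
    features (``gc_fraction``, ``has_polyT``) and the SNP flag
    (``snp_overlap``); ``pct_cds``, ``conservation_score`` and on-target
    score columns are optional refinements.
    """
    lo, hi = params.gc_bounds
    for g in guides:
        _require(
            g,
            ["n0", "n_mm12_offtargets", "n_mm12_coding_offtargets",
             "gc_fraction", "has_polyT", "snp_overlap"],
        )
        a = g.annotations
        unique = a["n0"] == 1
        if unique and a["n_mm12_coding_offtargets"] == 0:
            rnd = 1
        elif a["n_mm12_offtargets"] < params.max_mm_offtargets:
            rnd = 2
        else:
            rnd = 3
        if a["snp_overlap"] or a["has_polyT"] or not (lo <= a["gc_fraction"] <= hi):
            rnd = 4
        a["round"] = rnd
    comp = _composite_scores(guides, params)

    def order_key(g):
        a = g.annotations
        pct = _num(a.get("pct_cds"))
        in_cds_head = pct is not None and pct <= params.cds_cutoff_pct
        cons = _num(a.get("conservation_score"))
        conserved = cons is not None and cons > params.conservation_sign_cutoff
        return (a["round"], not in_cds_head, not conserved, -comp[g.id], g.id)

    return _finalise(guides, order_key)


def rank_guides_casrx(
    guides: GuideSet,
    params: RankingParams = RankingParams(),
    score_column: str | None = None,
) -> pd.DataFrame:
    """Multi-round ranking for RNA-targeting (CasRx-class) nucleases.

    Requires ``isoform_fraction``, alignment summaries and sequence
    features. Within-round order follows ``score_column`` (descending)
    when given, falling back as for Cas9.
    """
    r1, r2 = params.isoform_thresholds
    lo, hi = params.gc_bounds
    for g in guides:
        _require(
            g, ["isoform_fraction", "n_mm12_offtargets", "gc_fraction", "has_polyT"]
        )
        a = g.annotations
        frac = _num(a["isoform_fraction"], 0.0)
        clean = a["n_mm12_offtargets"] == 0
        if frac >= r1 and clean:
            rnd = 1
        elif frac >= r2 and clean:
            rnd = 2
        else:
            rnd = 3
        if a["has_polyT"] or not (lo <= a["gc_fraction"] <= hi):
            rnd = 4
        a["round"] = rnd
    if score_column:
        def score_of(g):
            return _num(g.annotations.get(score_column), 0.0)
    else:
        comp = _composite_scores(guides, params)

        def score_of(g):
            return comp[g.id]

    def order_key(g):
        return (g.annotations["round"], -score_of(g), g.id)

    return _finalise(guides, order_key)
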