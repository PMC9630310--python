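"""Mismatch-bounded on/off-target search with iterative escalation.

The search enumerates, for every guide, all subject windows within a Hamming
distance bound of the protospacer (no bulges), on both strands for DNA
targets and on the given strand only for RNA targets. The engine is a
pigeonhole seed-and-verify scan: a window with at most ``m`` mismatches must
contain at least one of ``m + 1`` equal partitions of the query verbatim, so
exact occurrences of each partition nominate candidate windows which are
then verified base by base. The contract is set equality with a naive
all-windows Hamming scan.

The iterative strategy mirrors genome-scale practice: align at 0 mismatches
first, then escalate the allowance one step at a time, but only for guides
whose cumulative hit count stays below a threshold — guides landing in
repeat elements stop escalating early, since they are already disqualified
for design purposes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .guides import Guide, GuideSet, _normalise_sequences
from .nucleases import Nuclease, cut_site, revcomp

CONTEXT_LEVELS = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "exon_noncoding",
    "intron",
    "intergenic",
)

PAM_MODES = ("canonical_only", "any_pam", "ignore_pam")


@dataclass
class AlignmentHit:
    """One (off-)target locus for one guide.

    ``mismatch_positions`` holds ``(p, spacer_base, subject_base)`` triples
    with ``p`` in 1..L counted from the PAM-distal end of the protospacer —
    the indexing convention of the CFD/MIT mismatch-weight tables.
    """

    guide_id: str
    subject_id: str
    pam_coordinate: int
    strand: str
    n_mismatches: int
    mismatch_positions: tuple[tuple[int, str, str], ...]
    pam_observed: str
    canonical_pam: bool
    is_on_target: bool = False
    cut_position: int | None = None
    context: str | None = None
    cutting_score: float | None = None

    @property
    def locus(self) -> tuple[str, int, str]:
        return (self.subject_id, self.pam_coordinate, self.strand)

    def key(self) -> tuple:
        return (self.guide_id, self.subject_id, self.pam_coordinate, self.strand)


@dataclass
class AlignmentSummary:
    guide_id: str
    counts: dict[int, int | None] = field(default_factory=dict)
    escalation_stopped_at: int | None = None

    def n(self, m: int) -> int | None:
        return self.counts.get(m)


# ---------------------------------------------------------------------------
# Core windowed Hamming search
# ---------------------------------------------------------------------------


def _candidate_windows(text: str, query: str, max_mm: int):
    """Candidate window starts via pigeonhole partitioning of the query."""
    L = len(query)
    n = len(text)
    if n < L:
        return
    k = max_mm + 1
    if k >= L:
        yield from range(n - L + 1)
        return
    seen = set()
    base = L // k
    extra = L % k
    off = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        chunk = query[off : off + size]
        pos = text.find(chunk)
        while pos != -1:
            s = pos - off
            if 0 <= s <= n - L and s not in seen:
                seen.add(s)
                yield s
            pos = text.find(chunk, pos + 1)
        off += size


def _verify(text: str, s: int, query: str, max_mm: int) -> list[int] | None:
    """Mismatch indices of window ``text[s:s+L]`` vs ``query`` or None."""
    mm: list[int] = []
    for i, q in enumerate(query):
        if text[s + i] != q:
            mm.append(i)
            if len(mm) > max_mm:
                return None
    return mm


def _hits_one_strand(
    guide: Guide,
    nuclease: Nuclease,
    subject_id: str,
    text: str,
    strand: str,
    max_mm: int,
    pam_mode: str,
) -> list[AlignmentHit]:
    """Hits of one guide on one strand; ``text`` is already oriented so the
    protospacer reads 5'->3' left to right (revcomp of the subject for the
    minus strand)."""
    query = guide.protospacer.upper()
    L = len(query)
    plen = nuclease.pam_length
    n = len(text)
    hits = []
    for s in _candidate_windows(text, query, max_mm):
        mm = _verify(text, s, query, max_mm)
        if mm is None:
            continue
        if nuclease.pam_side == "3prime":
            if s + L + plen > n:
                continue
            pam = text[s + L : s + L + plen]
            coord_scan = s + L
        elif nuclease.pam_side == "5prime":
            if s - plen < 0:
                continue
            pam = text[s - plen : s]
            coord_scan = s - plen
        else:
            pam = ""
            coord_scan = s + L
        canonical = nuclease.is_canonical_pam(pam)
        if pam_mode == "canonical_only" and not canonical:
            continue
        if pam_mode == "any_pam" and not (
            canonical or nuclease.pam_weight(pam) > 0.0
        ):
            continue
        coord = coord_scan if strand == "+" else n - 1 - coord_scan
        if nuclease.pam_side == "5prime":
            positions = tuple((L - i, query[i], text[s + i]) for i in reversed(mm))
        else:
            positions = tuple((i + 1, query[i], text[s + i]) for i in mm)
        hits.append(
            AlignmentHit(
                guide_id=guide.id,
                subject_id=subject_id,
                pam_coordinate=coord,
                strand=strand,
                n_mismatches=len(mm),
                mismatch_positions=positions,
                pam_observed=pam,
                canonical_pam=canonical,
                is_on_target=(subject_id, coord, strand) == guide.locus,
                cut_position=cut_site(coord, strand, nuclease),
            )
        )
    return hits


def find_alignments(
    guides: GuideSet,
    subject,
    max_mismatches: int,
    pam_mode: str = "canonical_only",
) -> list[AlignmentHit]:
    """Complete enumeration of subject windows within the mismatch bound.

    Every window within Hamming distance ``max_mismatches`` of a guide's
    protospacer, whose adjacent PAM satisfies ``pam_mode``, is reported
    exactly once. DNA targets are searched on both strands; RNA targets on
    the plus strand of the supplied (transcript) sequences only.
    """
    nuc = guides.nuclease
    if pam_mode not in PAM_MODES:
        raise ValueError(f"unknown pam_mode {pam_mode!r}")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if max_mismatches > nuc.spacer_length:
        raise ValueError("max_mismatches exceeds the spacer length")
    seqs = _normalise_sequences(subject)
    strands = ["+"] if nuc.target_type == "RNA" else ["+", "-"]
    hits: list[AlignmentHit] = []
    for subject_id, text in seqs.items():
        oriented = {"+": text}
        if "-" in strands:
            oriented["-"] = revcomp(text)
        for g in guides:
            for strand in strands:
                hits.extend(
                    _hits_one_strand(
                        g, nuc, subject_id, oriented[strand], strand,
                        max_mismatches, pam_mode,
                    )
                )
    hits.sort(key=AlignmentHit.key)
    return hits


def summarize_alignments(
    guides: GuideSet, hits: list[AlignmentHit], max_mismatches: int
) -> dict[str, AlignmentSummary]:
    """Per-guide hit counts at each mismatch level (on-target included)."""
    summaries = {
        g.id: AlignmentSummary(g.id, {m: 0 for m in range(max_mismatches + 1)})
        for g in guides
    }
    for h in hits:
        summaries[h.guide_id].counts[h.n_mismatches] += 1
    return summaries


def find_alignments_iterative(
    guides: GuideSet,
    subject,
    max_mismatches: int,
    escalation_threshold: float = 100,
    pam_mode: str = "canonical_only",
) -> tuple[list[AlignmentHit], dict[str, AlignmentSummary]]:
    """Mismatch-bounded search with per-guide escalation control.

    Aligns all guides at 0 mismatches, then raises the allowance one level at
    a time, continuing only for guides whose cumulative hit count has not
    exceeded ``escalation_threshold``. For a guide stopped at level ``k`` the
    summary records ``escalation_stopped_at = k`` and levels above ``k`` as
    not computed (``None``); for all other guides the hits are identical to
    :func:`find_alignments`.
    """
    if escalation_threshold < 1:
        raise ValueError("escalation_threshold must be >= 1")
    nuc = guides.nuclease
    summaries = {
        g.id: AlignmentSummary(g.id, {m: None for m in range(max_mismatches + 1)})
        for g in guides
    }
    cumulative = {g.id: 0 for g in guides}
    active = list(guides)
    all_hits: list[AlignmentHit] = []
    for level in range(max_mismatches + 1):
        if not active:
            break
        subset = GuideSet(active, nuc, dict(guides.provenance))
        level_hits = [
            h
            for h in find_alignments(subset, subject, level, pam_mode)
            if h.n_mismatches == level
        ]
        per_guide = {g.id: 0 for g in active}
        for h in level_hits:
            per_guide[h.guide_id] += 1
        all_hits.extend(level_hits)
        still_active = []
        for g in active:
            summaries[g.id].counts[level] = per_guide[g.id]
            cumulative[g.id] += per_guide[g.id]
            if cumulative[g.id] > escalation_threshold:
                summaries[g.id].escalation_stopped_at = level
            else:
                still_active.append(g)
        active = still_active
    all_hits.sort(key=AlignmentHit.key)
    return all_hits, summaries


# ---------------------------------------------------------------------------
# Genic context of hits
# ---------------------------------------------------------------------------


def annotate_hit_context(hits: list[AlignmentHit], gene_model) -> list[AlignmentHit]:
    """Label each hit with the highest-priority genic feature at its cut site.

    Priority: CDS > UTRs > non-coding exon > intron > intergenic. Hits on
    sequences absent from the gene model get ``context=None`` with a
    warning. The hit's cut position is used when defined, otherwise the
    representative PAM coordinate.
    """
    known = gene_model.seq_ids()
    missing = set()
    out = []
    for h in hits:
        if h.subject_id not in known:
            missing.add(h.subject_id)
            out.append(replace(h, context=None))
            continue
        point = h.cut_position if h.cut_position is not None else h.pam_coordinate
        out.append(replace(h, context=gene_model.context_at(h.subject_id, point)))
    if missing:
        warnings.warn(
            f"sequences absent from gene model: {sorted(missing)}", stacklevel=2
        )
    return out


def attach_alignment_annotations(
    guides: GuideSet,
    hits: list[AlignmentHit],
    summaries: dict[str, AlignmentSummary] | None = None,
    max_mismatches: int = 3,
) -> GuideSet:
    """Fold per-guide alignment counts into guide annotations for ranking.

    Adds ``n0..n{max}`` total hit counts (on-target included), the count of
    1-2 mismatch off-targets, and the count of 1-2 mismatch off-targets whose
    cut site falls in a CDS (requires :func:`annotate_hit_context` first;
    unlabeled hits count as non-coding).
    """
    if summaries is None:
        summaries = summarize_alignments(guides, hits, max_mismatches)
    coding = {g.id: 0 for g in guides}
    for h in hits:
        if h.n_mismatches in (1, 2) and h.context == "CDS":
            coding[h.guide_id] += 1
    for g in guides:
        s = summaries.get(g.id)
        counts = s.counts if s else {}
        for m in range(max_mismatches + 1):
            g.annotations[f"n{m}"] = counts.get(m)
        n1 = counts.get(1) or 0
        n2 = counts.get(2) or 0
        g.annotations["n_mm12_offtargets"] = n1 + n2
        g.annotations["n_mm12_coding_offtargets"] = coding[g.id]
        g.annotations["escalation_stopped_at"] = (
            s.escalation_stopped_at if s else None
        )
    return guides
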