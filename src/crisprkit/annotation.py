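"""Gene-model, TSS, SNP and conservation annotation of guides, plus
allele-injected genome construction.

The gene model is a GTF/GFF3 subset (exon and CDS features carrying
``transcript_id``/``gene_id`` attributes, optionally a ``canonical`` tag)
indexed with interval trees per sequence. All genomic arithmetic is 0-based
half-open; GTF input/output is converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .guides import GuideSet, _normalise_sequences
from .nucleases import pam_interval

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    id: str
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    canonical: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


class GeneModel:
    """Transcript structures with per-sequence interval indexes."""

    def __init__(self, transcripts: Mapping[str, Transcript]):
        self.transcripts = dict(transcripts)
        for tx in self.transcripts.values():
            tx.exons.sort()
            tx.cds.sort()
            if tx.cds:
                cds_span = (tx.cds[0][0], tx.cds[-1][1])
                for s, e in tx.cds:
                    if not any(es <= s and e <= ee for es, ee in tx.exons):
                        raise ValueError(
                            f"CDS {s}-{e} of {tx.id} not contained in its exons"
                        )
                if tx.cds_length() % 3 != 0:
                    warnings.warn(
                        f"CDS length of {tx.id} not divisible by 3", stacklevel=2
                    )
                tx._cds_span = cds_span
        self._genes: dict[str, list[str]] = {}
        for tid, tx in self.transcripts.items():
            self._genes.setdefault(tx.gene_id, []).append(tid)
        self._build_trees()

    def _build_trees(self):
        self._tx_tree: dict[str, IntervalTree] = {}
        self._exon_tree: dict[str, IntervalTree] = {}
        self._cds_tree: dict[str, IntervalTree] = {}
        self._utr5_tree: dict[str, IntervalTree] = {}
        self._utr3_tree: dict[str, IntervalTree] = {}
        for tid, tx in self.transcripts.items():
            sid = tx.seq_id
            for d in (self._tx_tree, self._exon_tree, self._cds_tree,
                      self._utr5_tree, self._utr3_tree):
                d.setdefault(sid, IntervalTree())
            s, e = tx.span
            self._tx_tree[sid][s:e] = tid
            for es, ee in tx.exons:
                self._exon_tree[sid][es:ee] = tid
            for cs, ce in tx.cds:
                self._cds_tree[sid][cs:ce] = tid
            if tx.cds:
                c0, c1 = tx._cds_span
                for es, ee in tx.exons:
                    left = (max(es, 0), min(ee, c0))
                    right = (max(es, c1), ee)
                    for (us, ue), side in ((left, "left"), (right, "right")):
                        if us >= ue:
                            continue
                        five = (side == "left") == (tx.strand == "+")
                        tree = self._utr5_tree if five else self._utr3_tree
                        tree[sid][us:ue] = tid

    # -- queries ------------------------------------------------------------

    def seq_ids(self) -> set[str]:
        return set(self._tx_tree)

    def gene_isoforms(self, gene_id: str) -> list[str]:
        return sorted(self._genes.get(gene_id, []))

    def context_at(self, seq_id: str, point: int) -> str:
        """Highest-priority genic feature overlapping one position."""
        if self._cds_tree.get(seq_id, IntervalTree()).at(point):
            return "CDS"
        if self._utr5_tree.get(seq_id, IntervalTree()).at(point):
            return "five_prime_UTR"
        if self._utr3_tree.get(seq_id, IntervalTree()).at(point):
            return "three_prime_UTR"
        if self._exon_tree.get(seq_id, IntervalTree()).at(point):
            return "exon_noncoding"
        if self._tx_tree.get(seq_id, IntervalTree()).at(point):
            return "intron"
        return "intergenic"

    def transcripts_at(
        self, seq_id: str, point: int, cds_only: bool = False
    ) -> list[str]:
        tree = self._cds_tree if cds_only else self._tx_tree
        return sorted({iv.data for iv in tree.get(seq_id, IntervalTree()).at(point)})

    def transcripts_overlapping(
        self, seq_id: str, start: int, end: int, exonic: bool = True
    ) -> list[str]:
        tree = self._exon_tree if exonic else self._tx_tree
        return sorted(
            {iv.data for iv in tree.get(seq_id, IntervalTree()).overlap(start, end)}
        )

    def cds_index(self, transcript_id: str, genomic_pos: int) -> int | None:
        """0-based index of a genomic position within the spliced CDS, in
        translation order; None if the position is not coding."""
        tx = self.transcripts[transcript_id]
        offset = 0
        pieces = tx.cds if tx.strand == "+" else list(reversed(tx.cds))
        for s, e in pieces:
            if s <= genomic_pos < e:
                return offset + (
                    genomic_pos - s if tx.strand == "+" else e - 1 - genomic_pos
                )
            offset += e - s
        return None

    def cds_sequence(self, transcript_id: str, genome: Mapping[str, str]) -> str:
        tx = self.transcripts[transcript_id]
        text = genome[tx.seq_id]
        spliced = "".join(text[s:e] for s, e in tx.cds)
        return spliced if tx.strand == "+" else _rc(spliced)

    def canonical_transcript(self, gene_id: str) -> str | None:
        tids = self.gene_isoforms(gene_id)
        for tid in tids:
            if self.transcripts[tid].canonical:
                return tid
        return tids[0] if tids else None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GeneModel":
        """Build from a GTF/GFF3 subset with exon and CDS features."""
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        transcripts: dict[str, Transcript] = {}
        for f in db.all_features():
            if f.featuretype not in ("exon", "CDS"):
                continue
            tid = f.attributes["transcript_id"][0]
            gid = f.attributes.get("gene_id", [tid])[0]
            tx = transcripts.setdefault(
                tid,
                Transcript(
                    id=tid, gene_id=gid, seq_id=f.seqid, strand=f.strand
                ),
            )
            interval = (f.start - 1, f.end)  # GTF is 1-based inclusive
            if f.featuretype == "exon":
                tx.exons.append(interval)
            else:
                tx.cds.append(interval)
            if "canonical" in f.attributes.get("tag", []):
                tx.canonical = True
        return cls(transcripts)


# ---------------------------------------------------------------------------
# Guide annotations
# ---------------------------------------------------------------------------


def _guide_point(guide) -> int:
    return (
        guide.cut_position
        if guide.cut_position is not None
        else guide.pam_coordinate
    )


def add_gene_annotation(
    guides: GuideSet,
    gene_model: GeneModel,
    atg_min_offset: int = 0,
) -> GuideSet:
    """Gene-level annotations: targeted isoforms, %CDS position, downstream
    in-frame ATG.

    A transcript is targeted when the protospacer interval overlaps its
    exons. ``pct_cds`` is the percent position of the cut within the
    spliced CDS of the gene's canonical transcript (only when the cut is
    coding). ``downstream_inframe_atg`` flags an in-frame ATG codon at
    least ``atg_min_offset`` codons 3' of the cut codon within the same
    CDS — a minimal, configurable translation-reinitiation heuristic.
    """
    for g in guides:
        point = _guide_point(g)
        targeted = gene_model.transcripts_overlapping(g.seq_id, g.start, g.end)
        genes = sorted({gene_model.transcripts[t].gene_id for t in targeted})
        iso_frac = None
        gene_id = None
        if genes:
            fracs = {
                gid: len([t for t in targeted
                          if gene_model.transcripts[t].gene_id == gid])
                / len(gene_model.gene_isoforms(gid))
                for gid in genes
            }
            gene_id = max(fracs, key=lambda k: (fracs[k], k))
            iso_frac = fracs[gene_id]
        pct_cds = None
        atg = False
        if gene_id is not None:
            canon = gene_model.canonical_transcript(gene_id)
            if canon is not None:
                idx = gene_model.cds_index(canon, point)
                if idx is not None:
                    clen = gene_model.transcripts[canon].cds_length()
                    pct_cds = 100.0 * (idx + 1) / clen
        pct_per_tx = {}
        for t in targeted:
            idx = gene_model.cds_index(t, point)
            if idx is not None:
                pct_per_tx[t] = 100.0 * (idx + 1) / gene_model.transcripts[t].cds_length()
        g.annotations.update(
            targeted_transcripts=",".join(targeted),
            gene_id=gene_id,
            isoform_fraction=iso_frac,
            pct_cds=pct_cds,
            pct_cds_per_transcript=";".join(
                f"{t}:{v:.2f}" for t, v in sorted(pct_per_tx.items())
            ),
        )
    return guides


def add_downstream_atg_flag(
    guides: GuideSet,
    gene_model: GeneModel,
    genome,
    atg_min_offset: int = 0,
) -> GuideSet:
    """Flag guides whose cut precedes an in-frame ATG in the same CDS.

    Requires :func:`add_gene_annotation` first (uses the annotated gene).
    The flag is a placeholder for published translation-reinitiation rules:
    any ATG codon at least ``atg_min_offset`` codons downstream of the cut
    codon, in frame, within the canonical CDS.
    """
    seqs = _normalise_sequences(genome)
    for g in guides:
        flag = False
        gene_id = g.annotations.get("gene_id")
        if gene_id:
            canon = gene_model.canonical_transcript(gene_id)
            idx = (
                gene_model.cds_index(canon, _guide_point(g))
                if canon is not None
                else None
            )
            if idx is not None:
                cds = gene_model.cds_sequence(canon, seqs)
                cut_codon = idx // 3
                for c in range(cut_codon + 1 + atg_min_offset, len(cds) // 3):
                    if cds[3 * c : 3 * c + 3] == "ATG":
                        flag = True
                        break
        g.annotations["downstream_inframe_atg"] = flag
    return guides


def casrx_isoform_annotation(
    guides: GuideSet,
    gene_model: GeneModel,
    transcript_seqs: Mapping[str, str],
) -> GuideSet:
    """Isoform fractions for transcriptome-designed (RNA-targeting) guides.

    Guides are discovered on individual transcript sequences; an isoform of
    the parent gene is targeted when it contains the guide's protospacer
    verbatim.
    """
    seqs = _normalise_sequences(transcript_seqs)
    for g in guides:
        if g.seq_id not in gene_model.transcripts:
            g.annotations.setdefault("isoform_fraction", None)
            continue
        gene_id = gene_model.transcripts[g.seq_id].gene_id
        isoforms = gene_model.gene_isoforms(gene_id)
        hit = [
            t for t in isoforms if g.protospacer in seqs.get(t, "")
        ]
        g.annotations.update(
            gene_id=gene_id,
            targeted_transcripts=",".join(hit),
            isoform_fraction=len(hit) / len(isoforms),
        )
    return guides


def add_tss_annotation(
    guides: GuideSet,
    tss_table: pd.DataFrame,
    window: tuple[int, int] = (75, 150),
) -> GuideSet:
    """Distance to the nearest TSS and an activation-window flag.

    Distances are strand-aware and signed: negative means the cut lies
    upstream of the TSS. ``in_window`` is true when the distance falls in
    [-b, -a] for window (a, b) — the CRISPRa default is 75-150 nt upstream.
    """
    a, b = window
    for g in guides:
        point = _guide_point(g)
        best = None
        rows = tss_table[tss_table["seq_id"] == g.seq_id] if "seq_id" in tss_table else tss_table
        for r in rows.itertuples():
            dist = point - int(r.tss) if r.strand == "+" else int(r.tss) - point
            if best is None or abs(dist) < abs(best[1]):
                best = (r.gene, dist)
        if best is None:
            g.annotations.update(tss_gene=None, dist_to_tss=None, tss_in_window=False)
        else:
            g.annotations.update(
                tss_gene=best[0],
                dist_to_tss=best[1],
                tss_in_window=-b <= best[1] <= -a,
            )
    return guides


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A VCF-subset record: 0-based position, REF/ALT, alt-allele frequency."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    af: float | None = None

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def add_snp_annotation(
    guides: GuideSet, variants: Iterable[Variant]
) -> GuideSet:
    """Flag guides whose target site (protospacer plus PAM) overlaps a variant."""
    nuc = guides.nuclease
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for g in guides:
        ps, pe = g.start, g.end
        qs, qe = pam_interval(g.pam_coordinate, g.strand, nuc)
        lo, hi = min(ps, qs), max(pe, qe)
        ids = [
            v.id
            for v in by_chrom.get(g.seq_id, [])
            if v.pos < hi and v.pos + max(1, len(v.ref)) > lo
        ]
        g.annotations.update(snp_overlap=bool(ids), snp_ids=",".join(ids))
    return guides


def add_conservation(
    guides: GuideSet, track: Mapping[str, np.ndarray], window: int = 18
) -> GuideSet:
    """Mean conservation score in a window centred on the cut site.

    The default 18-nt window spans [cut - 9, cut + 9). Bases missing from
    the track (NaN) are excluded from the mean, not imputed; a fully
    missing window yields NaN.
    """
    half = window // 2
    for g in guides:
        point = _guide_point(g)
        arr = track.get(g.seq_id)
        score = float("nan")
        if arr is not None:
            lo = max(0, point - half)
            hi = min(len(arr), point + (window - half))
            vals = arr[lo:hi]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                score = float(vals.mean())
        g.annotations["conservation_score"] = score
    return guides


# ---------------------------------------------------------------------------
# Allele injection
# ---------------------------------------------------------------------------


def inject_alleles(
    genome: Mapping[str, str],
    variants: Iterable[Variant],
    mode: str = "major",
) -> dict[str, str]:
    """Replace each SNV position with the major (or minor) allele.

    The AF field is the alternate-allele frequency: in ``major`` mode the
    ALT base is injected when AF > 0.5, in ``minor`` mode when AF < 0.5
    (ties keep REF in major mode and inject ALT in minor mode). Indels are
    excluded with a warning; a REF base disagreeing with the genome is a
    hard error. Output sequences have the same length as the input.
    """
    if mode not in ("major", "minor"):
        raise ValueError(f"unknown mode {mode!r}")
    seqs = {k: list(v) for k, v in _normalise_sequences(genome).items()}
    skipped = 0
    for v in variants:
        if not v.is_snv:
            skipped += 1
            continue
        if v.chrom not in seqs:
            raise ValueError(f"variant {v.id} on unknown sequence {v.chrom}")
        current = seqs[v.chrom][v.pos]
        if current != v.ref.upper():
            raise ValueError(
                f"REF mismatch for {v.id} at {v.chrom}:{v.pos}: "
                f"genome has {current}, record says {v.ref}"
            )
        if v.af is None:
            raise ValueError(f"variant {v.id} lacks an allele frequency")
        use_alt = v.af > 0.5 if mode == "major" else v.af < 0.5
        if use_alt:
            seqs[v.chrom][v.pos] = v.alt.upper()
    if skipped:
        warnings.warn(f"excluded {skipped} non-SNV variants", stacklevel=2)
    return {k: "".join(v) for k, v in seqs.items()}
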