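"""Deterministic synthetic-data generators for every input format.

Every generator is seeded and byte-reproducible: the same spec always
yields the same genome, gene model, variants, conservation track and
screen table. Genomes are i.i.d. random sequences at a configurable GC
content with guide target sites planted at known, recorded loci — the
truth tables close the loop with the off-target search. The screen
generator emulates a FACS-style single-mismatch (SM) tiling screen for an
RNA-targeting nuclease: perfect-match (PM) guides draw positive log fold
changes, and each SM guide's LFC is its parent's LFC scaled by a known
position-dependent mismatch tolerance weight plus noise; recovering those
weights is the benchmark for the CFD-CasRx estimation procedure.

What these fixtures do not emulate: chromatin context, repeat families
beyond exact planted repeats, sequencing noise models, or realistic human
base composition beyond GC content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneModel, Transcript, Variant
from .guides import Guide, GuideSet
from .nucleases import (
    IUPAC_SETS,
    Nuclease,
    cut_site,
    pam_coordinate,
    protospacer_interval,
    revcomp,
)

DEFAULT_SEED = 20221102

BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Bundle of generator parameters; field defaults are the conditions
    the test-suite fixtures run under."""

    seed: int = DEFAULT_SEED
    genome_length: int = 100_000
    gc: float = 0.41
    n_guides: int = 50
    copies_per_guide: Mapping[int, int] = dc_field(
        default_factory=lambda: {0: 1, 1: 1, 2: 1, 3: 1}
    )
    n_genes: int = 3
    transcripts_per_gene: int = 2
    exons_per_transcript: int = 3
    variant_density: float = 1.0  # variants per kb
    track_segment_length: int = 500
    spacer_length: int | None = None


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _concrete_pam(rng: np.random.Generator, pattern: str) -> str:
    return "".join(sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))]
                   for c in pattern)


def _mutate(rng: np.random.Generator, seq: str, n_mm: int) -> str:
    out = list(seq)
    for i in rng.choice(len(seq), size=n_mm, replace=False):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def make_genome(
    spec: FixtureSpec,
    nuclease: Nuclease,
    seq_id: str = "chr1",
    max_retries: int = 200,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with guide target sites planted at recorded loci.

    For each of ``n_guides`` random spacers, one copy per requested
    mismatch count is written into the genome (with a concrete canonical
    PAM where the nuclease needs one), on a random strand for DNA
    nucleases, at non-overlapping positions. Returns the genome and a
    truth table with one row per planted copy (guide index, spacer,
    coordinates, strand, mismatch count).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.spacer_length or nuclease.spacer_length
    genome = list(_random_sequence(rng, spec.genome_length, spec.gc))
    plen = nuclease.pam_length
    site_len = L + plen
    used: list[tuple[int, int]] = []
    rows = []

    def free(s: int, e: int) -> bool:
        return all(e <= us or s >= ue for us, ue in used)

    for gi in range(spec.n_guides):
        protospacer = _random_sequence(rng, L, 0.5)
        for n_mm in sorted(spec.copies_per_guide):
            for _ in range(spec.copies_per_guide[n_mm]):
                planted = _mutate(rng, protospacer, n_mm)
                if plen:
                    pattern = [
                        p.pattern for p in nuclease.pam_patterns if p.weight == 1.0
                    ][0]
                    pam = _concrete_pam(rng, pattern)
                else:
                    pam = ""
                if nuclease.pam_side == "5prime":
                    site = pam + planted
                else:
                    site = planted + pam
                strand = (
                    "+"
                    if nuclease.target_type == "RNA"
                    else ("+", "-")[rng.integers(2)]
                )
                placed = False
                for _ in range(max_retries):
                    s = int(rng.integers(0, spec.genome_length - site_len + 1))
                    if not free(s, s + site_len):
                        continue
                    text = site if strand == "+" else revcomp(site)
                    genome[s : s + site_len] = list(text)
                    used.append((s, s + site_len))
                    if nuclease.pam_side == "5prime":
                        pam_start = s if strand == "+" else s + L
                    else:
                        pam_start = s + L if strand == "+" else s
                    coord = pam_coordinate(pam_start, plen, strand)
                    if plen == 0 and strand == "+":
                        coord = s + L
                    rows.append(
                        {
                            "guide_index": gi,
                            "spacer": protospacer,
                            "planted_protospacer": planted,
                            "seq_id": seq_id,
                            "pam_coordinate": coord,
                            "strand": strand,
                            "pam": pam,
                            "n_mismatches": n_mm,
                        }
                    )
                    placed = True
                    break
                if not placed:
                    raise RuntimeError(
                        f"could not place copy of guide {gi} after {max_retries} tries"
                    )
    truth = pd.DataFrame(rows).sort_values(
        ["guide_index", "n_mismatches", "pam_coordinate"]
    ).reset_index(drop=True)
    return {seq_id: "".join(genome)}, truth


def guideset_from_truth(
    truth: pd.DataFrame, nuclease: Nuclease, provenance: dict | None = None
) -> GuideSet:
    """Build the GuideSet whose on-target loci are the planted 0-mismatch
    copies recorded in a truth table (first exact copy per guide)."""
    guides = []
    for gi, grp in truth.groupby("guide_index"):
        exact = grp[grp.n_mismatches == 0].iloc[0]
        protospacer = exact.spacer
        strand = exact.strand
        coord = int(exact.pam_coordinate)
        start, end = protospacer_interval(coord, strand, nuclease)
        guides.append(
            Guide(
                id=f"g{gi:03d}",
                spacer=(
                    revcomp(protospacer)
                    if nuclease.target_type == "RNA"
                    else protospacer
                ),
                protospacer=protospacer,
                pam=exact.pam,
                seq_id=exact.seq_id,
                pam_coordinate=coord,
                strand=strand,
                start=start,
                end=end,
                cut_position=cut_site(coord, strand, nuclease),
            )
        )
    return GuideSet(guides, nuclease, dict(provenance or {}))


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def make_gene_model(
    spec: FixtureSpec, seq_id: str = "chr1"
) -> tuple[GeneModel, str, pd.DataFrame]:
    """Synthetic gene model: evenly spaced genes, nested isoforms.

    Each gene gets ``transcripts_per_gene`` isoforms sharing the gene's
    exon grid; isoform k uses all exons minus its last k, so isoform 0
    (flagged canonical) is the longest. CDS trims 30 nt off each end of
    the exon chain and rounds down to a multiple of 3. Returns the model,
    its GTF text, and a TSS table.
    """
    exon_len, intron_len, margin = 120, 80, 30
    gene_span = (
        spec.exons_per_transcript * exon_len
        + (spec.exons_per_transcript - 1) * intron_len
    )
    spacing = gene_span + 400
    transcripts: dict[str, Transcript] = {}
    tss_rows = []
    for gj in range(spec.n_genes):
        gene_start = 200 + gj * spacing
        if gene_start + gene_span > spec.genome_length:
            break
        strand = "+" if gj % 2 == 0 else "-"
        gene_id = f"gene{gj}"
        exons = [
            (
                gene_start + i * (exon_len + intron_len),
                gene_start + i * (exon_len + intron_len) + exon_len,
            )
            for i in range(spec.exons_per_transcript)
        ]
        tss_rows.append(
            {
                "gene": gene_id,
                "seq_id": seq_id,
                "tss": gene_start if strand == "+" else gene_start + gene_span - 1,
                "strand": strand,
            }
        )
        for tk in range(spec.transcripts_per_gene):
            n_exons = max(1, spec.exons_per_transcript - tk)
            tx_exons = exons[:n_exons] if strand == "+" else exons[-n_exons:]
            tid = f"{gene_id}.t{tk}"
            lo = tx_exons[0][0] + margin
            hi = tx_exons[-1][1] - margin
            pieces = [
                (max(s, lo), min(e, hi)) for s, e in tx_exons if min(e, hi) > max(s, lo)
            ]
            length = sum(e - s for s, e in pieces)
            trim = length % 3
            if trim:
                if strand == "+":
                    s, e = pieces[-1]
                    pieces[-1] = (s, e - trim)
                else:
                    s, e = pieces[0]
                    pieces[0] = (s + trim, e)
            transcripts[tid] = Transcript(
                id=tid,
                gene_id=gene_id,
                seq_id=seq_id,
                strand=strand,
                exons=list(tx_exons),
                cds=[p for p in pieces if p[1] > p[0]],
                canonical=(tk == 0),
            )
    model = GeneModel(transcripts)
    gtf = gene_model_to_gtf(model)
    return model, gtf, pd.DataFrame(tss_rows)


def gene_model_to_gtf(model: GeneModel) -> str:
    """GTF text (1-based inclusive) for a gene model."""
    lines = []
    for tid in sorted(model.transcripts):
        tx = model.transcripts[tid]
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tid}";'
        if tx.canonical:
            attrs += ' tag "canonical";'
        for kind, intervals in (("exon", tx.exons), ("CDS", tx.cds)):
            for s, e in intervals:
                lines.append(
                    "\t".join(
                        [
                            tx.seq_id, "crisprkit", kind, str(s + 1), str(e),
                            ".", tx.strand, ".", attrs,
                        ]
                    )
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Variants and conservation tracks
# ---------------------------------------------------------------------------


def make_variants(
    spec: FixtureSpec, genome: Mapping[str, str]
) -> list[Variant]:
    """Random SNVs at ``variant_density`` per kb with uniform allele
    frequencies in [0.01, 0.99]."""
    rng = np.random.default_rng(spec.seed + 1)
    out = []
    i = 0
    for chrom in sorted(genome):
        text = genome[chrom]
        n = int(round(spec.variant_density * len(text) / 1000))
        positions = np.sort(
            rng.choice(len(text), size=min(n, len(text)), replace=False)
        )
        for pos in positions:
            ref = text[pos]
            if ref not in "ACGT":
                continue
            alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
            out.append(
                Variant(
                    chrom=chrom,
                    pos=int(pos),
                    id=f"rs{i}",
                    ref=ref,
                    alt=alt,
                    af=float(np.round(rng.uniform(0.01, 0.99), 4)),
                )
            )
            i += 1
    return out


def make_track(
    spec: FixtureSpec, genome: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Piecewise-constant conservation scores (phyloP-like, mean 0)."""
    rng = np.random.default_rng(spec.seed + 2)
    track = {}
    for chrom in sorted(genome):
        n = len(genome[chrom])
        n_seg = math.ceil(n / spec.track_segment_length)
        values = rng.normal(0.0, 1.0, size=n_seg)
        arr = np.repeat(values, spec.track_segment_length)[:n]
        track[chrom] = np.round(arr, 3)
    return track


# ---------------------------------------------------------------------------
# Pooled screen simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedScreen:
    """A simulated PM/SM/DM tiling screen with its generating truth."""

    table: pd.DataFrame  # guide_id, parent_id, type, positions, lfc
    true_weights: dict[int, float]
    pm_median_lfc: float

    def sm_delta_table(self) -> pd.DataFrame:
        """(position, delta_lfc) rows for the weight-estimation procedure."""
        pm = self.table[self.table.type == "PM"].set_index("guide_id").lfc
        sm = self.table[self.table.type == "SM"]
        return pd.DataFrame(
            {
                "position": sm.positions.astype(int).to_numpy(),
                "delta_lfc": sm.lfc.to_numpy() - pm.loc[sm.parent_id].to_numpy(),
            }
        )


def default_weight_profile(L: int = 23) -> dict[int, float]:
    """Smooth position->tolerance profile used as screen-simulation truth:
    mismatches near the spacer centre cost most activity."""
    return {
        p: round(0.35 + 0.55 * math.cos(math.pi * (p - 1) / (L - 1)) ** 2, 4)
        for p in range(1, L + 1)
    }


def make_screen_table(
    seed: int = DEFAULT_SEED,
    n_pm: int = 25,
    n_sm: int = 500,
    n_dm: int = 0,
    spacer_length: int = 23,
    weights: Mapping[int, float] | None = None,
    pm_lfc_mean: float = 2.0,
    pm_lfc_sd: float = 0.2,
    noise_sd: float = 0.05,
) -> SimulatedScreen:
    """Simulate a FACS-style PM/SM(/DM) tiling screen.

    PM guides draw LFC ~ Normal(pm_lfc_mean, pm_lfc_sd) truncated positive
    (enrichment convention). Each SM guide picks a PM parent and a mismatch
    position and draws LFC = w(p) * LFC_PM + noise; DM guides multiply two
    position weights. The generating weights are returned as truth.

    The default spread parameters define the small-noise regime the
    weight-estimation procedure is specified for: parent heterogeneity does
    not cancel in the SM-minus-PM differences (it enters scaled by w - 1),
    so defaults are set a priori such that the position-level standard
    error of the estimated activity weight stays near a third of the 0.05
    recovery tolerance.
    """
    rng = np.random.default_rng(seed)
    w = dict(weights or default_weight_profile(spacer_length))
    rows = []
    pm_lfcs = np.maximum(rng.normal(pm_lfc_mean, pm_lfc_sd, size=n_pm), 0.2)
    for i, lfc in enumerate(pm_lfcs):
        rows.append(
            {"guide_id": f"pm{i}", "parent_id": "", "type": "PM",
             "positions": "", "lfc": float(lfc)}
        )
    for j in range(n_sm):
        parent = int(rng.integers(n_pm))
        p = int(rng.integers(1, spacer_length + 1))
        lfc = w[p] * pm_lfcs[parent] + rng.normal(0.0, noise_sd)
        rows.append(
            {"guide_id": f"sm{j}", "parent_id": f"pm{parent}", "type": "SM",
             "positions": str(p), "lfc": float(lfc)}
        )
    for k in range(n_dm):
        parent = int(rng.integers(n_pm))
        p1, p2 = sorted(
            rng.choice(np.arange(1, spacer_length + 1), size=2, replace=False)
        )
        lfc = w[p1] * w[p2] * pm_lfcs[parent] + rng.normal(0.0, noise_sd)
        rows.append(
            {"guide_id": f"dm{k}", "parent_id": f"pm{parent}", "type": "DM",
             "positions": f"{p1};{p2}", "lfc": float(lfc)}
        )
    table = pd.DataFrame(rows)
    return SimulatedScreen(
        table=table,
        true_weights=w,
        pm_median_lfc=float(np.median(pm_lfcs)),
    )
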