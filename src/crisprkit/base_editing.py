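"""Base-editor outcome enumeration and scoring.

A base editor's behaviour is a 3-d array of editing probabilities
q(p, nuc_u, nuc_e): the probability that the original nucleotide nuc_u is
converted to nuc_e at window position p (relative to the PAM-first-base
coordinate). Assuming independence of editing events across positions, the
likelihood of an edited allele V against wildtype U is the product of the
per-position outcome probabilities; over the full (untruncated) enumeration
these likelihoods sum to 1. Each allele is labelled with its most
consequential protein-level effect (nonsense over missense over silent),
and per-guide mutation-type scores are the sums of member-allele
likelihoods.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

from Bio.Data.CodonTable import standard_dna_table

from .guides import Guide, _normalise_sequences
from .nucleases import BaseEditor

CONSEQUENCES = ("nonsense", "missense", "silent", "none")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class EditedAllele:
    """One enumerated editing outcome within a guide's editing window.

    ``ref``/``alt`` are the wildtype and edited base vectors in
    protospacer-strand orientation, aligned with ``positions`` (relative to
    the PAM-first base) and ``genomic_positions`` (plus-strand, 0-based).
    """

    positions: tuple[int, ...]
    genomic_positions: tuple[int, ...]
    ref: tuple[str, ...]
    alt: tuple[str, ...]
    score: float
    consequence: str = "none"
    protein_change: str = ""

    @property
    def is_identity(self) -> bool:
        return self.ref == self.alt


def enumerate_edited_alleles(
    guide: Guide,
    editor: BaseEditor,
    genomic_context,
    min_score: float = 1e-4,
) -> list[EditedAllele]:
    """All editable-window outcomes with likelihood >= ``min_score``.

    Only window positions with at least one off-diagonal editing
    probability for the wildtype base branch the enumeration, so the
    combinatorial blow-up is bounded by the true number of editable bases.
    The identity allele is included (when its mass clears the threshold);
    before thresholding the scores of the full enumeration sum to 1.
    """
    seqs = _normalise_sequences(genomic_context)
    if guide.seq_id not in seqs:
        raise ValueError(f"context lacks sequence {guide.seq_id!r}")
    text = seqs[guide.seq_id]
    sign = 1 if guide.strand == "+" else -1
    per_position: list[tuple[int, int, str, list[tuple[str, float]]]] = []
    for p in editor.window_positions:
        g = guide.pam_coordinate + sign * p
        if not (0 <= g < len(text)):
            raise ValueError(
                f"editing window position {p} falls outside the context"
            )
        proto_base = text[g] if guide.strand == "+" else _COMP[text[g]]
        # q is indexed by bases on the editing strand
        u = proto_base if editor.editing_strand == "protospacer" else _COMP[proto_base]
        outcomes = editor.outcomes(p, u)
        per_position.append((p, g, proto_base, outcomes))
    branching = [pp for pp in per_position if len(pp[3]) > 1 or pp[3][0][0] != (
        pp[2] if editor.editing_strand == "protospacer" else _COMP[pp[2]])]
    static = [pp for pp in per_position if pp not in branching]
    # score mass carried by the non-branching positions (their single outcome)
    base_mass = 1.0
    for _, _, _, outcomes in static:
        base_mass *= outcomes[0][1]
    alleles: list[EditedAllele] = []
    choice_lists = [pp[3] for pp in branching]
    for combo in itertools.product(*choice_lists):
        score = base_mass
        for (_, prob) in combo:
            score *= prob
        if score < min_score:
            continue
        edited = {}
        for (p, g, proto_base, _), (e, _) in zip(branching, combo):
            alt = e if editor.editing_strand == "protospacer" else _COMP[e]
            edited[p] = alt
        positions = tuple(pp[0] for pp in per_position)
        gpos = tuple(pp[1] for pp in per_position)
        ref = tuple(pp[2] for pp in per_position)
        alt = tuple(edited.get(pp[0], pp[2]) for pp in per_position)
        alleles.append(
            EditedAllele(
                positions=positions,
                genomic_positions=gpos,
                ref=ref,
                alt=alt,
                score=score,
            )
        )
    alleles.sort(key=lambda a: (-a.score, a.alt))
    return alleles


# ---------------------------------------------------------------------------
# Functional consequence
# ---------------------------------------------------------------------------


def _translate_codon(codon: str, table) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def classify_consequence(
    wildtype_cds: str,
    edited_cds: str,
    codon_table=standard_dna_table,
) -> tuple[str, str]:
    """Protein-level label of an edited coding sequence vs wildtype.

    Both sequences must be in-frame and of equal length. Each changed codon
    is classified (stop gain = nonsense, amino-acid change = missense,
    synonymous = silent) and the allele takes the most consequential label:
    nonsense over missense over silent; no nucleotide change gives 'none'.
    Returns ``(label, protein_change)`` with HGVS-like change strings such
    as ``Q4*``.
    """
    wt = wildtype_cds.upper()
    ed = edited_cds.upper()
    if len(wt) != len(ed):
        raise ValueError("wildtype and edited CDS lengths differ")
    if len(wt) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    changes: dict[str, list[str]] = {"nonsense": [], "missense": [], "silent": []}
    for i in range(0, len(wt), 3):
        cw, ce = wt[i : i + 3], ed[i : i + 3]
        if cw == ce:
            continue
        aw = _translate_codon(cw, codon_table)
        ae = _translate_codon(ce, codon_table)
        change = f"{aw}{i // 3 + 1}{ae}"
        if ae == "*" and aw != "*":
            changes["nonsense"].append(change)
        elif ae != aw:
            changes["missense"].append(change)
        else:
            changes["silent"].append(change)
    for label in ("nonsense", "missense", "silent"):
        if changes[label]:
            return label, ";".join(changes[label])
    return "none", ""


def annotate_allele_consequences(
    alleles: Sequence[EditedAllele],
    guide: Guide,
    gene_model,
    genome,
    transcript_id: str | None = None,
) -> list[EditedAllele]:
    """Label each allele using the CDS of one transcript from the gene model.

    The transcript defaults to the canonical transcript whose CDS overlaps
    any window position; alleles whose edits all fall outside the CDS are
    labelled 'none'. Splice-site effects are not modelled.
    """
    seqs = _normalise_sequences(genome)
    if transcript_id is None:
        for g in sorted(alleles[0].genomic_positions) if alleles else []:
            tids = gene_model.transcripts_at(guide.seq_id, g, cds_only=True)
            if tids:
                canonical = [t for t in tids if gene_model.transcripts[t].canonical]
                transcript_id = (canonical or sorted(tids))[0]
                break
    if transcript_id is None:
        return [replace(a, consequence="none", protein_change="") for a in alleles]
    wt_cds = gene_model.cds_sequence(transcript_id, seqs)
    tx = gene_model.transcripts[transcript_id]
    out = []
    for a in alleles:
        cds = list(wt_cds)
        touched = False
        for g, ref, alt in zip(a.genomic_positions, a.ref, a.alt):
            if ref == alt:
                continue
            idx = gene_model.cds_index(transcript_id, g)
            if idx is None:
                continue
            plus_base = alt if guide.strand == "+" else _COMP[alt]
            cds[idx] = plus_base if tx.strand == "+" else _COMP[plus_base]
            touched = True
        if not touched:
            out.append(replace(a, consequence="none", protein_change=""))
            continue
        label, change = classify_consequence(wt_cds, "".join(cds))
        out.append(replace(a, consequence=label, protein_change=change))
    return out


# ---------------------------------------------------------------------------
# Per-guide aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationScores:
    silent: float
    missense: float
    nonsense: float


def aggregate_mutation_scores(alleles: Sequence[EditedAllele]) -> MutationScores:
    """Sum allele likelihoods per mutation type.

    Identity and non-coding ('none') alleles absorb the remaining mass, so
    silent + missense + nonsense <= 1, with equality plus the 'none' mass on
    an untruncated enumeration.
    """
    totals = {"silent": 0.0, "missense": 0.0, "nonsense": 0.0}
    for a in alleles:
        if a.consequence in totals:
            totals[a.consequence] += a.score
    return MutationScores(**totals)
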