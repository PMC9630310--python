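"""Readers and writers for the package's interchange formats.

Tables are tab-separated with '#'-prefixed header comments carrying
provenance (tool version, config hash, seed) and '.' for missing values.
Genomic coordinates are 0-based half-open everywhere except GFF3 export
(1-based inclusive) and VCF (1-based positions).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .annotation import Variant
from .guides import Guide, GuideSet
from .nucleases import load_nuclease
from .offtargets import AlignmentHit

MISSING = "."


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance_header(provenance: Mapping | None) -> list[str]:
    lines = [f"# crisprkit_version={__version__}"]
    for key, value in sorted((provenance or {}).items()):
        if isinstance(value, (dict, list)):
            value = json.dumps(value, sort_keys=True)
        lines.append(f"# {key}={value}")
    return lines


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Generic provenance-stamped TSV
# ---------------------------------------------------------------------------


def write_tsv(
    df: pd.DataFrame, path: str | Path, provenance: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        for line in provenance_header(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])


# ---------------------------------------------------------------------------
# GuideSet round-trip
# ---------------------------------------------------------------------------

_GUIDE_CORE = [
    "id", "spacer", "protospacer", "pam", "seq_id", "pam_coordinate",
    "strand", "start", "end", "cut_position",
]


def write_guideset(guides: GuideSet, path: str | Path) -> None:
    """GuideSet as TSV with a sidecar JSON provenance file.

    The sidecar records the provenance mapping and the full nuclease
    definition, so a written set can be read back without other inputs.
    """
    path = Path(path)
    write_tsv(guides.to_frame(), path, guides.provenance)
    nuc = guides.nuclease
    sidecar = {
        "provenance": guides.provenance,
        "nuclease": {
            "name": nuc.name,
            "target_type": nuc.target_type,
            "pam_side": nuc.pam_side,
            "pam_patterns": [[p.pattern, p.weight] for p in nuc.pam_patterns],
            "spacer_length": nuc.spacer_length,
            "cut_offset": nuc.cut_offset,
        },
    }
    with open(path.with_suffix(path.suffix + ".provenance.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_guideset(path: str | Path) -> GuideSet:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".provenance.json")) as fh:
        sidecar = json.load(fh)
    nd = dict(sidecar["nuclease"])
    if nd.get("pam_side") == "none":
        nd.pop("pam_patterns", None)
    nuclease = load_nuclease(nd)
    df = read_tsv(path)
    guides = []
    for _, row in df.iterrows():
        core = {k: row[k] for k in _GUIDE_CORE}
        cut = core["cut_position"]
        core["cut_position"] = None if pd.isna(cut) else int(cut)
        core["pam_coordinate"] = int(core["pam_coordinate"])
        core["start"], core["end"] = int(core["start"]), int(core["end"])
        core["pam"] = "" if pd.isna(core["pam"]) else str(core["pam"])
        annotations = {
            k: (None if pd.isna(v) else v)
            for k, v in row.items()
            if k not in _GUIDE_CORE
        }
        guides.append(Guide(**core, annotations=annotations))
    return GuideSet(guides, nuclease, sidecar["provenance"])


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------


def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "guide_id": h.guide_id,
                "subject_id": h.subject_id,
                "pam_coordinate": h.pam_coordinate,
                "strand": h.strand,
                "n_mismatches": h.n_mismatches,
                "mismatches": ";".join(
                    f"{p}:{a}>{b}" for p, a, b in h.mismatch_positions
                ),
                "pam_observed": h.pam_observed,
                "canonical_pam": h.canonical_pam,
                "is_on_target": h.is_on_target,
                "cut_position": h.cut_position,
                "context": h.context,
                "cutting_score": h.cutting_score,
            }
        )
    return pd.DataFrame(rows)


def write_hits(
    hits: Iterable[AlignmentHit], path: str | Path, provenance=None
) -> None:
    write_tsv(hits_to_frame(hits), path, provenance)


# ---------------------------------------------------------------------------
# BED / GFF export
# ---------------------------------------------------------------------------


def guides_to_bed6(guides: GuideSet, path: str | Path) -> None:
    """Protospacer intervals as BED6; the score column is the composite
    on-target score when annotated, '.' otherwise."""
    with open(path, "w") as fh:
        for g in guides:
            score = g.annotations.get("composite_score")
            score_txt = MISSING if score is None else f"{score:.4f}"
            fh.write(
                f"{g.seq_id}\t{g.start}\t{g.end}\t{g.id}\t{score_txt}\t{g.strand}\n"
            )


def guides_to_gff3(guides: GuideSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in guides:
            attrs = f"ID={g.id};spacer={g.spacer};pam={g.pam}"
            fh.write(
                "\t".join(
                    [
                        g.seq_id, "crisprkit", "protospacer",
                        str(g.start + 1), str(g.end), MISSING, g.strand,
                        MISSING, attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Conservation tracks
# ---------------------------------------------------------------------------


def read_bedgraph(
    path: str | Path, lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base score arrays from a bedGraph; uncovered bases are NaN."""
    track = {k: np.full(n, np.nan) for k, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom in track:
                track[chrom][int(start) : int(end)] = float(value)
    return track


def write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode per-base arrays back to bedGraph (NaN = no line)."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = track[chrom]
            start = None
            value = None
            for i, v in enumerate(arr):
                if np.isnan(v):
                    if start is not None:
                        fh.write(f"{chrom}\t{start}\t{i}\t{value:g}\n")
                        start = None
                elif start is None or v != value:
                    if start is not None:
                        fh.write(f"{chrom}\t{start}\t{i}\t{value:g}\n")
                    start, value = i, v
            if start is not None:
                fh.write(f"{chrom}\t{start}\t{len(arr)}\t{value:g}\n")


def read_wiggle(
    path: str | Path, lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Fixed-step wiggle reader (step/span default 1); uncovered bases NaN."""
    track = {k: np.full(n, np.nan) for k, n in lengths.items()}
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                continue
            if chrom in track:
                track[chrom][pos : pos + span] = float(line)
            pos += step
    return track


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> list[Variant]:
    """Variants (first ALT allele, INFO:AF) from an uncompressed VCF."""
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            out.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    id=rec.id or MISSING,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else rec.ref,
                    af=None if af is None else float(af),
                )
            )
    return out


def write_vcf(
    variants: Iterable[Variant], path: str | Path, contigs: Mapping[str, int]
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,'
            'Description="Alternate allele frequency">\n'
        )
        for name, length in sorted(contigs.items()):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            af = MISSING if v.af is None else f"AF={v.af:g}"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t{af}\n"
            )
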