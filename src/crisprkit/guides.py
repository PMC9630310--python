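"""Candidate guide discovery and sequence-derived design features.

Scans input sequences for every position where a tolerated PAM pattern
matches and a full-length protospacer fits, producing a :class:`GuideSet`.
For DNA-targeting nucleases both strands are searched by scanning the
reverse complement and mirroring coordinates back; RNA-targeting nucleases
(Cas13 family) search the given strand only, and their spacer is the reverse
complement of the target protospacer.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .nucleases import (
    Nuclease,
    cut_site,
    iupac_regex,
    pam_coordinate,
    protospacer_interval,
    revcomp,
)


@dataclass
class Guide:
    """One candidate gRNA at one genomic (or transcriptomic) locus.

    ``spacer`` is the gRNA sequence (5'->3'); for DNA nucleases it equals the
    protospacer, for RNA nucleases it is the protospacer's reverse
    complement. ``start``/``end`` is the plus-strand half-open interval of
    the protospacer; ``pam_coordinate`` follows the PAM-first-base
    convention. ``annotations`` is an open record filled by later stages.
    """

    id: str
    spacer: str
    protospacer: str
    pam: str
    seq_id: str
    pam_coordinate: int
    strand: str
    start: int
    end: int
    cut_position: int | None = None
    annotations: dict = field(default_factory=dict)

    @property
    def locus(self) -> tuple[str, int, str]:
        return (self.seq_id, self.pam_coordinate, self.strand)


@dataclass
class GuideSet:
    guides: list[Guide]
    nuclease: Nuclease
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        loci = [g.locus for g in self.guides]
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate (seq_id, pam_coordinate, strand) in GuideSet")

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self):
        return iter(self.guides)

    def __getitem__(self, i):
        return self.guides[i]

    def by_id(self) -> dict[str, Guide]:
        return {g.id: g for g in self.guides}

    def to_frame(self) -> pd.DataFrame:
        """Flatten guides plus accumulated annotations into a DataFrame."""
        rows = []
        for g in self.guides:
            row = {
                "id": g.id,
                "spacer": g.spacer,
                "protospacer": g.protospacer,
                "pam": g.pam,
                "seq_id": g.seq_id,
                "pam_coordinate": g.pam_coordinate,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "cut_position": g.cut_position,
            }
            row.update(g.annotations)
            rows.append(row)
        return pd.DataFrame(rows)


def _normalise_sequences(sequences) -> dict[str, str]:
    """Accept a mapping id->sequence or an iterable of SeqRecord-likes."""
    if isinstance(sequences, Mapping):
        return {str(k): str(v).upper() for k, v in sequences.items()}
    out = {}
    for rec in sequences:
        out[str(rec.id)] = str(rec.seq).upper()
    return out


def _scan_strand(
    text: str, nuclease: Nuclease, min_weight: float
) -> Iterable[tuple[int, str, str]]:
    """Yield (pam_start_in_text, protospacer, pam) for one strand's text.

    PAM-free nucleases yield every window where a protospacer fits, with the
    'PAM start' being the position immediately 3' of the protospacer.
    """
    L = nuclease.spacer_length
    n = len(text)
    if nuclease.pam_side == "none":
        for s in range(0, n - L + 1):
            yield s + L, text[s : s + L], ""
        return
    patterns = [p.pattern for p in nuclease.pam_patterns if p.weight >= min_weight]
    if not patterns:
        return
    rx = re.compile("(?=(" + "|".join(iupac_regex(p) for p in patterns) + "))")
    plen = nuclease.pam_length
    for m in rx.finditer(text):
        s = m.start()
        if nuclease.pam_side == "3prime":
            if s - L < 0 or s + plen > n:
                continue
            yield s, text[s - L : s], text[s : s + plen]
        else:  # 5prime
            if s + plen + L > n:
                continue
            yield s, text[s + plen : s + plen + L], text[s : s + plen]


def find_spacers(
    sequences,
    nuclease: Nuclease,
    both_strands: bool = True,
    min_pam_weight: float = 1e-12,
    provenance: dict | None = None,
) -> GuideSet:
    """Enumerate all candidate guides for a nuclease in the input sequences.

    Every position where a PAM pattern with weight > 0 (or
    ``>= min_pam_weight``) matches and the full protospacer fits inside the
    sequence yields exactly one guide. Protospacer and PAM must be fully
    contained; guides are returned sorted by (seq_id, pam_coordinate,
    strand).
    """
    seqs = _normalise_sequences(sequences)
    if not seqs:
        raise ValueError("no input sequences")
    if nuclease.target_type == "RNA" and both_strands:
        raise ValueError("RNA-targeting nucleases search a single strand")
    guides: list[Guide] = []
    for seq_id in seqs:
        text = seqs[seq_id]
        n = len(text)
        strands = ["+", "-"] if both_strands else ["+"]
        for strand in strands:
            scan_text = text if strand == "+" else revcomp(text)
            for pam_start, protospacer, pam in _scan_strand(
                scan_text, nuclease, min_pam_weight
            ):
                if "N" in protospacer:
                    continue
                if strand == "+":
                    coord = pam_coordinate(pam_start, nuclease.pam_length, "+")
                else:
                    # map the scanned (revcomp) coordinate back to plus strand:
                    # the PAM's 5'-most base in scan coords is pam_start
                    coord = n - 1 - pam_start
                start, end = protospacer_interval(coord, strand, nuclease)
                spacer = (
                    revcomp(protospacer)
                    if nuclease.target_type == "RNA"
                    else protospacer
                )
                guides.append(
                    Guide(
                        id="",
                        spacer=spacer,
                        protospacer=protospacer,
                        pam=pam,
                        seq_id=seq_id,
                        pam_coordinate=coord,
                        strand=strand,
                        start=start,
                        end=end,
                        cut_position=cut_site(coord, strand, nuclease),
                    )
                )
    guides.sort(key=lambda g: (g.seq_id, g.pam_coordinate, g.strand))
    for g in guides:
        g.id = f"{g.seq_id}_{g.pam_coordinate}{g.strand}"
    return GuideSet(
        guides=guides,
        nuclease=nuclease,
        provenance=dict(provenance or {}),
    )


# ---------------------------------------------------------------------------
# Sequence-derived features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceFeatures:
    gc_fraction: float
    has_polyT: bool
    max_homopolymer: int
    restriction_hits: tuple[str, ...]
    hairpin_flag: bool
    ops_prefix: str


def _max_homopolymer(seq: str) -> int:
    return max(len(list(run)) for _, run in itertools.groupby(seq)) if seq else 0


def _has_hairpin(seq: str, stem: int) -> bool:
    """Two disjoint substrings of length >= ``stem`` that are reverse
    complements of each other — a simple, configurable self-complementarity
    rule standing in for a thermodynamic hairpin model."""
    n = len(seq)
    for i in range(n - 2 * stem + 1):
        probe = revcomp(seq[i : i + stem])
        if seq.find(probe, i + stem) != -1:
            return True
    return False


def _restriction_sites(
    context: str, enzymes: Mapping[str, str] | None
) -> tuple[str, ...]:
    if not enzymes:
        return ()
    hits = []
    rc = revcomp(context)
    for name in sorted(enzymes):
        rx = re.compile(iupac_regex(enzymes[name].upper()))
        if rx.search(context) or rx.search(rc):
            hits.append(name)
    return tuple(hits)


def sequence_features(
    guide: Guide,
    enzymes: Mapping[str, str] | None = None,
    ops_cycles: int = 12,
    flank5: str = "",
    flank3: str = "",
    hairpin_stem: int = 5,
) -> SequenceFeatures:
    """Compute library-design features for one guide's spacer.

    GC fraction, the polyT termination signal and homopolymer length are
    computed on the spacer alone; restriction motifs are searched in the
    spacer plus user-supplied cloning-vector flanks, on both strands. The
    OPS prefix is the first ``ops_cycles`` bases read by partial in-situ
    sequencing.
    """
    spacer = guide.spacer.upper()
    if not spacer:
        raise ValueError("empty spacer")
    gc = (spacer.count("G") + spacer.count("C")) / len(spacer)
    context = (flank5 + spacer + flank3).upper()
    return SequenceFeatures(
        gc_fraction=gc,
        has_polyT="TTTT" in spacer,
        max_homopolymer=_max_homopolymer(spacer),
        restriction_hits=_restriction_sites(context, enzymes),
        hairpin_flag=_has_hairpin(spacer, hairpin_stem),
        ops_prefix=spacer[:ops_cycles],
    )


def add_sequence_features(guides: GuideSet, **kwargs) -> GuideSet:
    """Attach :func:`sequence_features` fields to every guide's annotations."""
    for g in guides:
        f = sequence_features(g, **kwargs)
        g.annotations.update(
            gc_fraction=f.gc_fraction,
            has_polyT=f.has_polyT,
            max_homopolymer=f.max_homopolymer,
            restriction_hits=",".join(f.restriction_hits),
            hairpin_flag=f.hairpin_flag,
            ops_prefix=f.ops_prefix,
        )
    return guides


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def ops_collisions(
    guides: GuideSet | Iterable[Guide], cycles: int = 12, min_hamming: int = 2
) -> pd.DataFrame:
    """Pairs of guides whose length-``cycles`` spacer prefixes are too similar.

    A pair is reported iff the Hamming distance between the two prefixes is
    below ``min_hamming`` — such guides cannot be distinguished by ``cycles``
    rounds of optical in-situ sequencing.
    """
    glist = list(guides)
    if cycles <= 0:
        raise ValueError("cycles must be positive")
    for g in glist:
        if cycles > len(g.spacer):
            raise ValueError("cycles exceeds spacer length")
    ids = [g.id for g in glist]
    if len(glist) < 2:
        return pd.DataFrame(columns=["guide1", "guide2", "hamming"])
    mat = np.array(
        [[_BASE_CODE.get(c, 4) for c in g.spacer[:cycles]] for g in glist],
        dtype=np.uint8,
    )
    rows = []
    for i in range(len(glist) - 1):
        d = (mat[i + 1 :] != mat[i]).sum(axis=1)
        for off in np.nonzero(d < min_hamming)[0]:
            j = i + 1 + int(off)
            rows.append((ids[i], ids[j], int(d[off])))
    return pd.DataFrame(rows, columns=["guide1", "guide2", "hamming"])
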