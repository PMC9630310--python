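"""Nuclease and base-editor models, and the genome arithmetic built on them.

A CRISPR nuclease is described declaratively: where its PAM sits relative to
the protospacer (3', 5', or absent), which PAM sequences it tolerates (IUPAC
patterns with tolerance weights in [0, 1]), how long its spacer is, and where
it cuts relative to the PAM. Every coordinate in the package is anchored on
one convention: the representative coordinate of a target site is the first
nucleotide of the PAM in the 5'->3' direction of the strand carrying the
protospacer. For PAM-free nucleases (e.g. Cas13 family used without a PFS
constraint) the representative coordinate is the base immediately 3' of the
protospacer, which keeps the arithmetic identical to a zero-length 3' PAM.

Coordinates are 0-based half-open internally; 1-based inclusive appears only
in exported GFF-style text.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Data.IUPACData import ambiguous_dna_values

# ---------------------------------------------------------------------------
# IUPAC helpers
# ---------------------------------------------------------------------------

#: Expansion of every IUPAC nucleotide code into the set of concrete bases.
#: Restricted to the standard code set (Biopython also accepts the
#: non-standard 'X', which we reject in PAM patterns).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code in "ACGTRYSWKMBDHVN"
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid_iupac(pattern: str) -> bool:
    return len(pattern) > 0 and all(c.upper() in IUPAC_SETS for c in pattern)


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a regex character-class string."""
    parts = []
    for c in pattern.upper():
        bases = sorted(IUPAC_SETS[c])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return "".join(parts)


def iupac_match(pattern: str, seq: str) -> bool:
    """Does ``seq`` match the IUPAC ``pattern`` exactly (case-insensitive)?

    ``N`` matches any concrete base, never a gap; lengths must be equal.
    """
    if len(pattern) != len(seq):
        return False
    return all(b.upper() in IUPAC_SETS[p.upper()] for p, b in zip(pattern, seq))


# ---------------------------------------------------------------------------
# Nuclease
# ---------------------------------------------------------------------------

PAM_SIDES = ("3prime", "5prime", "none")
TARGET_TYPES = ("DNA", "RNA")


@dataclass(frozen=True)
class PamPattern:
    pattern: str
    weight: float

    def __post_init__(self):
        if not is_valid_iupac(self.pattern):
            raise ValueError(f"invalid IUPAC PAM pattern: {self.pattern!r}")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(
                f"PAM tolerance weight must be in [0, 1], got {self.weight}"
            )


@dataclass(frozen=True)
class Nuclease:
    """A CRISPR nuclease: PAM model, spacer length and relative cut site.

    ``cut_offset`` is defined relative to the PAM-first-base coordinate along
    the protospacer strand. The cut site reported is the base immediately on
    the lower-coordinate side of the blunt-cut boundary; SpCas9's canonical
    cut 3 bp 5' of the PAM corresponds to ``cut_offset = -4``. ``None`` means
    the enzyme has no defined cut site (catalytically dead applications).
    """

    name: str
    target_type: str = "DNA"
    pam_side: str = "3prime"
    pam_patterns: tuple[PamPattern, ...] = ()
    spacer_length: int = 20
    cut_offset: int | None = None

    def __post_init__(self):
        if self.target_type not in TARGET_TYPES:
            raise ValueError(f"unknown target_type {self.target_type!r}")
        if self.pam_side not in PAM_SIDES:
            raise ValueError(f"unknown pam_side {self.pam_side!r}")
        if self.spacer_length < 1:
            raise ValueError("spacer_length must be >= 1")
        if self.pam_side == "none":
            if self.pam_patterns:
                raise ValueError("pam_side='none' implies no PAM patterns")
        else:
            if not self.pam_patterns:
                raise ValueError("a PAM-dependent nuclease needs >= 1 pattern")
            lengths = {len(p.pattern) for p in self.pam_patterns}
            if len(lengths) != 1:
                raise ValueError("all PAM patterns must share one length")
            if not any(p.weight == 1.0 for p in self.pam_patterns):
                raise ValueError("at least one PAM pattern must have weight 1")
        if self.target_type == "RNA" and self.pam_side == "5prime":
            raise ValueError("RNA-targeting nucleases use a 3' PFS or none")

    # -- PAM geometry -------------------------------------------------------

    @property
    def pam_length(self) -> int:
        return len(self.pam_patterns[0].pattern) if self.pam_patterns else 0

    def patterns_with_min_weight(self, min_weight: float) -> list[PamPattern]:
        return [p for p in self.pam_patterns if p.weight >= min_weight]

    def pam_weight(self, pam: str) -> float:
        """Largest tolerance weight of any pattern matching ``pam`` (0 if none)."""
        w = 0.0
        for p in self.pam_patterns:
            if p.weight > w and iupac_match(p.pattern, pam):
                w = p.weight
        return w

    def is_canonical_pam(self, pam: str) -> bool:
        return self.pam_side == "none" or any(
            p.weight == 1.0 and iupac_match(p.pattern, pam)
            for p in self.pam_patterns
        )


def pam_coordinate(pam_start: int, pam_length: int, strand: str) -> int:
    """Representative coordinate of a target site from its PAM interval.

    ``pam_start`` is the 0-based plus-strand start of the PAM interval
    (half-open, length ``pam_length``). On the plus strand the 5'-most PAM
    base is the interval start; on the minus strand it is the interval end
    minus one. Zero-length PAMs (PAM-free nucleases) pass the position of
    the base immediately 3' of the protospacer as ``pam_start``; on the minus
    strand that base's plus coordinate is ``pam_start - 1 + pam_length`` too,
    provided callers pass the half-open end of the minus-strand protospacer
    interval as ``pam_start`` — see :func:`protospacer_interval`.
    """
    if strand == "+":
        return pam_start
    if strand == "-":
        return pam_start + pam_length - 1 if pam_length > 0 else pam_start
    raise ValueError(f"unknown strand {strand!r}")


def cut_site(pam_coord: int, strand: str, nuclease: Nuclease) -> int | None:
    """Genomic cut position for a guide with the given representative coordinate.

    Returns ``None`` when the nuclease has no defined cut offset. The value is
    the base on the lower-coordinate (plus-strand) side of the blunt-cut
    boundary: ``pam + offset`` on the plus strand and ``pam - offset - 1`` on
    the minus strand, which places the cut at the homologous protospacer
    position on either strand.
    """
    if nuclease.cut_offset is None:
        return None
    if strand == "+":
        return pam_coord + nuclease.cut_offset
    if strand == "-":
        return pam_coord - nuclease.cut_offset - 1
    raise ValueError(f"unknown strand {strand!r}")


def protospacer_interval(
    pam_coord: int, strand: str, nuclease: Nuclease
) -> tuple[int, int]:
    """Plus-strand half-open interval occupied by the protospacer."""
    L = nuclease.spacer_length
    if nuclease.pam_side in ("3prime", "none"):
        if strand == "+":
            return pam_coord - L, pam_coord
        return pam_coord + 1, pam_coord + 1 + L
    # 5' PAM: protospacer sits 3' of the PAM on the protospacer strand
    plen = nuclease.pam_length
    if strand == "+":
        return pam_coord + plen, pam_coord + plen + L
    return pam_coord - plen - L + 1, pam_coord - plen + 1


def pam_interval(pam_coord: int, strand: str, nuclease: Nuclease) -> tuple[int, int]:
    """Plus-strand half-open interval occupied by the PAM (empty if none)."""
    plen = nuclease.pam_length
    if plen == 0:
        return pam_coord, pam_coord
    if nuclease.pam_side == "3prime":
        if strand == "+":
            return pam_coord, pam_coord + plen
        return pam_coord - plen + 1, pam_coord + 1
    if strand == "+":
        return pam_coord, pam_coord + plen
    return pam_coord - plen + 1, pam_coord + 1


# ---------------------------------------------------------------------------
# Base editors
# ---------------------------------------------------------------------------

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class BaseEditor:
    """A base editor: a nuclease plus a window of editing probabilities.

    ``q[(p, u, e)]`` is the probability that original nucleotide ``u`` is
    edited to ``e`` at position ``p`` relative to the PAM-first-base
    coordinate (negative positions are 5' of a 3' PAM, i.e. inside the
    protospacer). For every ``(p, u)`` the outcome row sums to 1, the
    identity outcome included; editors specified with off-diagonal weights
    only are completed by assigning the residual mass to identity.
    """

    base: Nuclease
    editing_strand: str = "protospacer"  # or "opposite"
    window_positions: tuple[int, ...] = ()
    q: Mapping[tuple[int, str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.editing_strand not in ("protospacer", "opposite"):
            raise ValueError(f"unknown editing_strand {self.editing_strand!r}")
        for (p, u, e), prob in self.q.items():
            if p not in self.window_positions:
                raise ValueError(f"q entry at position {p} outside window")
            if u not in NUCLEOTIDES or e not in NUCLEOTIDES:
                raise ValueError(f"non-ACGT nucleotide in q entry ({u}->{e})")
            if not (0.0 <= prob <= 1.0):
                raise ValueError(f"editing probability out of [0,1]: {prob}")
        for p in self.window_positions:
            for u in NUCLEOTIDES:
                total = sum(self.q.get((p, u, e), 0.0) for e in NUCLEOTIDES)
                if not math.isclose(total, 1.0, abs_tol=1e-9):
                    raise ValueError(
                        f"editing probabilities at (p={p}, {u}) sum to {total}"
                    )

    @property
    def name(self) -> str:
        return self.base.name

    def prob(self, p: int, u: str, e: str) -> float:
        return self.q.get((p, u, e), 0.0)

    def outcomes(self, p: int, u: str) -> list[tuple[str, float]]:
        """Possible edited bases at (p, u) with non-zero probability."""
        return [
            (e, self.q[(p, u, e)])
            for e in NUCLEOTIDES
            if self.q.get((p, u, e), 0.0) > 0.0
        ]


def _complete_identity(
    window: Iterable[int], entries: Mapping[tuple[int, str, str], float]
) -> dict[tuple[int, str, str], float]:
    """Assign residual probability mass to the identity outcome per (p, u)."""
    q = dict(entries)
    for p in window:
        for u in NUCLEOTIDES:
            off = sum(q.get((p, u, e), 0.0) for e in NUCLEOTIDES if e != u)
            if off > 1.0 + 1e-9:
                raise ValueError(
                    f"off-diagonal editing mass {off} > 1 at (p={p}, {u})"
                )
            q.setdefault((p, u, u), max(0.0, 1.0 - off))
    return q


# ---------------------------------------------------------------------------
# Loading from configuration records
# ---------------------------------------------------------------------------

_NUCLEASE_FIELDS = {
    "name",
    "target_type",
    "pam_side",
    "pam_patterns",
    "spacer_length",
    "cut_offset",
}


def load_nuclease(definition: Mapping) -> Nuclease:
    """Validate a structured nuclease definition and build a :class:`Nuclease`.

    Unknown fields are rejected so that typos in hand-edited configuration
    files fail loudly rather than silently using a default.
    """
    unknown = set(definition) - _NUCLEASE_FIELDS
    if unknown:
        raise ValueError(f"unknown nuclease fields: {sorted(unknown)}")
    missing = {"name", "pam_side", "pam_patterns", "spacer_length"} - set(definition)
    if missing and not (
        definition.get("pam_side") == "none" and missing == {"pam_patterns"}
    ):
        raise ValueError(f"missing nuclease fields: {sorted(missing)}")
    patterns = tuple(
        PamPattern(str(pat), float(w))
        for pat, w in definition.get("pam_patterns", [])
    )
    return Nuclease(
        name=str(definition["name"]),
        target_type=str(definition.get("target_type", "DNA")),
        pam_side=str(definition["pam_side"]),
        pam_patterns=patterns,
        spacer_length=int(definition["spacer_length"]),
        cut_offset=(
            None
            if definition.get("cut_offset") is None
            else int(definition["cut_offset"])
        ),
    )


def load_base_editor(definition: Mapping) -> BaseEditor:
    """Build a :class:`BaseEditor` from a structured definition.

    ``editing_weights`` entries are records with ``position``, ``from``,
    ``to`` and ``probability``; identity rows may be omitted and are
    completed automatically.
    """
    base = load_nuclease(definition["base"])
    window = tuple(int(p) for p in definition["window_positions"])
    entries: dict[tuple[int, str, str], float] = {}
    for rec in definition.get("editing_weights", []):
        key = (int(rec["position"]), str(rec["from"]).upper(), str(rec["to"]).upper())
        entries[key] = float(rec["probability"])
    q = _complete_identity(window, entries)
    return BaseEditor(
        base=base,
        editing_strand=str(definition.get("editing_strand", "protospacer")),
        window_positions=window,
        q=q,
    )


def _read_builtin(name: str) -> dict:
    text = resources.files("crisprkit.data").joinpath(f"{name}.json").read_text()
    return json.loads(text)


def builtin_nuclease(name: str) -> Nuclease:
    """Load one of the shipped nuclease definitions (SpCas9, AsCas12a, CasRx)."""
    return load_nuclease(_read_builtin(name.lower()))


def builtin_base_editor(name: str) -> BaseEditor:
    """Load a shipped base-editor definition (BE4max placeholder weights)."""
    return load_base_editor(_read_builtin(name.lower()))


def load_nuclease_file(path: str | Path) -> Nuclease:
    with open(path) as fh:
        return load_nuclease(json.load(fh))


def load_base_editor_file(path: str | Path) -> BaseEditor:
    with open(path) as fh:
        return load_base_editor(json.load(fh))
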