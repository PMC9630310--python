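"""Shared fixtures and the independent all-windows alignment oracle."""

from __future__ import annotations

import numpy as np
import pytest

import crisprkit as ck
from crisprkit.nucleases import iupac_match, revcomp


@pytest.fixture(scope="session")
def spcas9():
    return ck.builtin_nuclease("SpCas9")


@pytest.fixture(scope="session")
def ascas12a():
    return ck.builtin_nuclease("AsCas12a")


@pytest.fixture(scope="session")
def casrx():
    return ck.builtin_nuclease("CasRx")


@pytest.fixture(scope="session")
def be4max():
    return ck.builtin_base_editor("BE4max")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Naive all-windows Hamming oracle (independent of the pigeonhole engine):
# per guide, shifted numpy equality comparisons accumulate per-window
# mismatch counts over the full subject; PAM admissibility is then checked
# per accepted window in plain Python.
# ---------------------------------------------------------------------------


def _window_mismatches(text: str, query: str) -> np.ndarray:
    arr = np.frombuffer(text.encode(), dtype=np.uint8)
    L = len(query)
    n = len(arr) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int32)
    for i in range(L):
        mism += arr[i : i + n] != q[i]
    return mism


def _pam_ok(nuc, pam: str, pam_mode: str) -> bool:
    if nuc.pam_side == "none" or pam_mode == "ignore_pam":
        return True
    canonical = any(
        p.weight == 1.0 and iupac_match(p.pattern, pam) for p in nuc.pam_patterns
    )
    if pam_mode == "canonical_only":
        return canonical
    return canonical or any(
        p.weight > 0.0 and iupac_match(p.pattern, pam) for p in nuc.pam_patterns
    )


def oracle_hits(guides, subject, max_mm: int, pam_mode: str = "canonical_only"):
    """Set of (guide_id, subject_id, pam_coordinate, strand, n_mismatches)
    from a brute-force scan of every window of every subject sequence."""
    nuc = guides.nuclease
    L = nuc.spacer_length
    plen = nuc.pam_length
    strands = ["+"] if nuc.target_type == "RNA" else ["+", "-"]
    out = set()
    if hasattr(subject, "items"):
        seqs = {k: str(v).upper() for k, v in subject.items()}
    else:
        seqs = {r.id: str(r.seq).upper() for r in subject}
    for sid, plus in seqs.items():
        n = len(plus)
        texts = {"+": plus, "-": revcomp(plus)}
        for strand in strands:
            text = texts[strand]
            for g in guides:
                mism = _window_mismatches(text, g.protospacer.upper())
                for s in np.nonzero(mism <= max_mm)[0]:
                    s = int(s)
                    if nuc.pam_side == "3prime":
                        if s + L + plen > n:
                            continue
                        pam, coord_scan = text[s + L : s + L + plen], s + L
                    elif nuc.pam_side == "5prime":
                        if s - plen < 0:
                            continue
                        pam, coord_scan = text[s - plen : s], s - plen
                    else:
                        pam, coord_scan = "", s + L
                    if not _pam_ok(nuc, pam, pam_mode):
                        continue
                    coord = coord_scan if strand == "+" else n - 1 - coord_scan
                    out.add((g.id, sid, coord, strand, int(mism[s])))
    return out


def hit_keys(hits):
    return {
        (h.guide_id, h.subject_id, h.pam_coordinate, h.strand, h.n_mismatches)
        for h in hits
    }
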