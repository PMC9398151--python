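"""UMI extraction, assay assignment, family grouping and consensus building.

Reads are assigned to assays by their forward primer (the panel is
closed and every amplicon is <= 99 bp, so primer-anchored assignment
stands in for genome alignment); families are keyed by exact
``(assay_id, UMI)`` string equality -- no fuzzy UMI merging.  A family
yields a consensus read only when it holds at least ``min_reads``
members (default 3); each column takes the majority symbol when its
fraction reaches ``min_agreement`` (default 0.9) and ``N`` otherwise.
Ties never produce a base.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .panel import PatientPanel

MIN_FAMILY_READS = 3
MIN_AGREEMENT = 0.9

_SYMBOLS = b"ACGTN-"
_SYM_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}
_GAP = _SYM_INDEX[ord("-")]
_N = _SYM_INDEX[ord("N")]


@dataclass(frozen=True)
class AssignedRead:
    umi: str
    assay_id: str
    insert_seq: str  # read minus UMI
    n_primer_mismatches: int


@dataclass(frozen=True)
class UnassignedRead:
    name: str
    reason: str  # too_short | ambiguous_primer | no_primer_match


@dataclass
class UmiFamily:
    key: tuple[str, str]  # (assay_id, umi)
    reads: list[AssignedRead]

    @property
    def size(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class ConsensusRead:
    key: tuple[str, str]
    sequence: str
    family_size: int


def _hamming(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def demultiplex_read(
    name_seq: tuple[str, str],
    panel: PatientPanel,
    umi_length: int = 12,
    max_primer_mismatch: int = 2,
) -> AssignedRead | UnassignedRead:
    """Assign one read to the unique best-matching forward primer."""
    name, seq = name_seq
    min_primer = min(len(a.fwd_primer) for a in panel.assays)
    if len(seq) <= umi_length + min_primer:
        return UnassignedRead(name, "too_short")
    umi = seq[:umi_length]
    insert = seq[umi_length:]
    best: list[str] = []
    best_d = max_primer_mismatch + 1
    for a in panel.assays:
        d = _hamming(insert[: len(a.fwd_primer)], a.fwd_primer, max_primer_mismatch)
        if d < best_d:
            best_d, best = d, [a.assay_id]
        elif d == best_d:
            best.append(a.assay_id)
    if best_d > max_primer_mismatch:
        return UnassignedRead(name, "no_primer_match")
    if len(best) > 1:
        return UnassignedRead(name, "ambiguous_primer")
    return AssignedRead(umi=umi, assay_id=best[0], insert_seq=insert, n_primer_mismatches=best_d)


def demultiplex_reads(
    reads: Iterable[tuple[str, str]],
    panel: PatientPanel,
    umi_length: int = 12,
    max_primer_mismatch: int = 2,
) -> tuple[list[AssignedRead], list[UnassignedRead]]:
    """Batch assignment with an exact-primer fast path for the error-free bulk."""
    exact = {a.fwd_primer: a.assay_id for a in panel.assays}
    primer_lens = sorted({len(a.fwd_primer) for a in panel.assays})
    assigned: list[AssignedRead] = []
    unassigned: list[UnassignedRead] = []
    for name, seq in reads:
        insert = seq[umi_length:]
        hit = None
        for pl in primer_lens:
            hit = exact.get(insert[:pl])
            if hit is not None:
                assigned.append(AssignedRead(seq[:umi_length], hit, insert, 0))
                break
        if hit is None:
            res = demultiplex_read((name, seq), panel, umi_length, max_primer_mismatch)
            (assigned if isinstance(res, AssignedRead) else unassigned).append(res)
    return assigned, unassigned


def group_families(assigned: Iterable[AssignedRead]) -> list[UmiFamily]:
    """Partition assigned reads into families by exact (assay_id, UMI) key.

    Families are returned sorted by key so downstream output never
    depends on read input order.
    """
    buckets: dict[tuple[str, str], list[AssignedRead]] = defaultdict(list)
    for r in assigned:
        buckets[(r.assay_id, r.umi)].append(r)
    return [UmiFamily(key=k, reads=buckets[k]) for k in sorted(buckets)]


def _cigar_blocks(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _project_onto_anchor(read: str, anchor: str) -> bytes:
    """Symbols of ``read`` at each anchor column ('-' where the read is deleted).

    Global (NW) alignment via edlib; read bases inserted relative to the
    anchor do not vote (they have no anchor column).
    """
    aln = edlib.align(read, anchor, mode="NW", task="path")
    out = bytearray()
    qi = 0
    for n, op in _cigar_blocks(aln["cigar"]):
        if op in "=X":
            out.extend(read[qi: qi + n].encode())
            qi += n
        elif op == "I":  # present in read, absent in anchor
            qi += n
        elif op == "D":  # absent in read
            out.extend(b"-" * n)
    return bytes(out)


def build_consensus(
    family: UmiFamily,
    min_reads: int = MIN_FAMILY_READS,
    min_agreement: float = MIN_AGREEMENT,
) -> ConsensusRead | None:
    """Per-column majority consensus; ``None`` for families below ``min_reads``.

    Columns are those of the family's modal-length read; length-
    discordant members are globally aligned to it first.  A column emits
    the majority symbol when its fraction of the family reaches
    ``min_agreement``, ``N`` when no symbol does or the top symbols tie,
    and nothing when the majority symbol is a gap.
    """
    if family.size < min_reads:
        return None
    inserts = sorted(r.insert_seq for r in family.reads)
    if len(set(inserts)) == 1:  # unanimity fast path
        return ConsensusRead(family.key, inserts[0], family.size)
    len_counts = Counter(len(s) for s in inserts)
    modal_len = max(len_counts, key=lambda l: (len_counts[l], -l))
    anchor = next(s for s in inserts if len(s) == modal_len)
    L = modal_len
    counts = np.zeros((len(_SYMBOLS), L), dtype=np.int32)
    same = [s for s in inserts if len(s) == L]
    if same:
        mat = np.frombuffer("".join(same).encode(), dtype=np.uint8).reshape(len(same), L)
        for sym, idx in _SYM_INDEX.items():
            counts[idx] += (mat == sym).sum(axis=0, dtype=np.int32)
    for s in inserts:
        if len(s) != L:
            proj = np.frombuffer(_project_onto_anchor(s, anchor), dtype=np.uint8)
            for sym, idx in _SYM_INDEX.items():
                counts[idx] += (proj == sym).astype(np.int32)
    n = family.size
    top = counts.argmax(axis=0)
    topc = counts.max(axis=0)
    tied = (counts == topc).sum(axis=0) > 1
    frac_ok = topc >= min_agreement * n
    out = bytearray()
    for j in range(L):
        if tied[j] or not frac_ok[j]:
            out.append(ord("N"))
        elif top[j] == _GAP:
            continue  # majority deletion: column dropped
        else:
            out.append(_SYMBOLS[top[j]])
    return ConsensusRead(family.key, out.decode(), family.size)


def build_all_consensus(
    families: Sequence[UmiFamily],
    min_reads: int = MIN_FAMILY_READS,
    min_agreement: float = MIN_AGREEMENT,
) -> list[ConsensusRead]:
    out = []
    for fam in families:
        c = build_consensus(fam, min_reads, min_agreement)
        if c is not None:
            out.append(c)
    return out


def mean_family_size(families: Sequence[UmiFamily]) -> float:
    """Arithmetic mean size over ALL detected families, including size < 3."""
    if not families:
        raise ValueError("mean family size is undefined for an empty family list")
    return sum(f.size for f in families) / len(families)


def family_size_histogram(families: Sequence[UmiFamily]) -> Counter:
    return Counter(f.size for f in families)


def write_consensus_fasta(consensus: Iterable[ConsensusRead], path) -> None:
    with open(path, "w") as fh:
        for c in consensus:
            fh.write(f">{c.key[0]}:{c.key[1]} family_size={c.family_size}\n{c.sequence}\n")
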