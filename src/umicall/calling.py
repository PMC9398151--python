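"""Consensus alignment, pileup, variant calling and sample classification.

Consensus reads are aligned to their amplicon reference by global
affine alignment (match +1, mismatch -1, gap open -2, gap extend -1)
with terminal gap runs trimmed as coverage loss, indels are
left-normalized, and events are piled up per amplicon position.  The calling rules are deliberately asymmetric: a
solitary single-nucleotide variant needs more than six supporting
consensus reads, whereas an insertion or deletion is called from a
single consensus read.  An SNV seen with fewer reads is kept as
*provisional* and upgraded to *rescued* when another sample from the
same patient shows the identical variant with at least six consensus
reads.  Spike-in control molecules (the diagnostic ATG insertion) are
counted separately and never contribute to variant calls.

A sample is *positive* when any tumor-specific or resistance variant is
called or rescued; otherwise it is *negative*, downgraded to
*negative_low_input* when fewer than 50 cfDNA molecules were detected
at the tumor-specific locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .consensus import ConsensusRead
from .panel import (
    Assay,
    PatientPanel,
    SpikeInControl,
    TargetVariant,
    left_normalize_indel,
    spikein_signature,
)

SNV_MIN_READS = 7  # "more than six consensus reads"
INDEL_MIN_READS = 1  # "one consensus read only"
RESCUE_ANCHOR_READS = 6  # "at least six consensus reads" in another sample
LOW_INPUT_MOLECULES = 50
MIN_ALIGN_IDENTITY = 0.7

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -2, -1

TIMEPOINTS = ("presurgery", "surgery_start", "mobilization", "closure", "postsurgery")
POSITIVITY_LABELS = ("tumor_specific", "resistance")


# ---------------------------------------------------------------------------
# affine pairwise alignment (Gotoh)

_NEG = -(10 ** 9)


def align_affine(query: str, ref: str) -> tuple[int, list[tuple[str, int, int]]]:
    """Optimal global affine alignment of ``query`` to ``ref``.

    Returns ``(score, path)`` where path is a list of ``(op, qpos,
    rpos)``; ops are 'M' (match/mismatch, consuming both), 'I' (query
    base absent from ref) and 'D' (ref base absent from query).  The
    first base of a gap costs GAP_OPEN, each further base GAP_EXTEND.
    Terminal gap runs (a truncated or overhanging consensus end) are
    trimmed from the returned path: they are coverage loss, not
    variants.  An overlap-style alignment with free end gaps is
    deliberately not used -- it trades a near-end indel for a cheaper
    mismatch-plus-overhang, misplacing real variants close to the
    primers.
    """
    n, m = len(query), len(ref)
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in ref (query consumed)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in query (ref consumed)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    ptrM = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0=M,1=X,2=Y predecessor state
    ptrX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.uint8)
    q = query.encode()
    r = ref.encode()
    for i in range(1, n + 1):
        qi = q[i - 1]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        for j in range(1, m + 1):
            s = MATCH if qi == r[j - 1] else MISMATCH
            a, b, c = Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]
            if a >= b and a >= c:
                Mi[j] = a + s
            elif b >= c:
                Mi[j] = b + s
                ptrM[i, j] = 1
            else:
                Mi[j] = c + s
                ptrM[i, j] = 2
            a, b, c = Mi1[j] + GAP_OPEN, Xi1[j] + GAP_EXTEND, Yi1[j] + GAP_OPEN
            if a >= b and a >= c:
                Xi[j] = a
            elif b >= c:
                Xi[j] = b
                ptrX[i, j] = 1
            else:
                Xi[j] = c
                ptrX[i, j] = 2
            a, b, c = Mi[j - 1] + GAP_OPEN, Xi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND
            if c >= a and c >= b:
                Yi[j] = c
                ptrY[i, j] = 2
            elif a >= b:
                Yi[j] = a
            else:
                Yi[j] = b
                ptrY[i, j] = 1
    ends = ((int(M[n, m]), 0), (int(X[n, m]), 1), (int(Y[n, m]), 2))
    score, state = max(ends)
    i, j = n, m
    path: list[tuple[str, int, int]] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = ptrM[i, j]
            path.append(("M", i - 1, j - 1))
            i, j, state = i - 1, j - 1, prev
        elif state == 1:
            prev = ptrX[i, j] if j > 0 else 1
            path.append(("I", i - 1, j))
            i, state = i - 1, prev
        else:
            prev = ptrY[i, j] if i > 0 else 2
            path.append(("D", i, j - 1))
            j, state = j - 1, prev
    path.reverse()
    # trim leading/trailing gap runs: they are overhang, not variants
    while path and path[0][0] != "M":
        path.pop(0)
    while path and path[-1][0] != "M":
        path.pop()
    return int(score), path


# ---------------------------------------------------------------------------
# event extraction


@dataclass(frozen=True)
class Event:
    kind: str  # SNV | INS | DEL
    pos: int  # 0-based amplicon coordinate (leftmost after normalization)
    ref: str
    alt: str

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


@dataclass
class AlignedConsensus:
    consensus: ConsensusRead
    assay_id: str
    ref_span: tuple[int, int]  # half-open aligned interval on the amplicon
    events: list[Event]
    n_positions: list[int]  # amplicon positions where the consensus holds N
    identity: float
    is_spikein: bool = False


def _events_from_path(query: str, ref: str, path: list[tuple[str, int, int]]) -> tuple[list[Event], list[int]]:
    events: list[Event] = []
    n_positions: list[int] = []
    i = 0
    while i < len(path):
        op, qp, rp = path[i]
        if op == "M":
            qb = query[qp]
            if qb == "N":
                n_positions.append(rp)
            elif qb != ref[rp]:
                events.append(Event("SNV", rp, ref[rp], qb))
            i += 1
        elif op == "I":
            j = i
            ins = []
            while j < len(path) and path[j][0] == "I":
                ins.append(query[path[j][1]])
                j += 1
            pos, _, alt = left_normalize_indel(ref, rp, "", "".join(ins))
            if "N" not in alt:
                events.append(Event("INS", pos, "", alt))
            i = j
        else:  # D
            j = i
            del_run = []
            while j < len(path) and path[j][0] == "D":
                del_run.append(ref[path[j][2]])
                j += 1
            pos, dref, _ = left_normalize_indel(ref, rp, "".join(del_run), "")
            events.append(Event("DEL", pos, dref, ""))
            i = j
    return events, n_positions


def align_consensus(consensus: ConsensusRead, assay: Assay) -> AlignedConsensus | None:
    """Align a consensus read to its amplicon; ``None`` when unalignable.

    Equal-length consensus sequences take a positional fast path (exact
    for up to two substitutions, where no gapped alignment can score
    higher); everything else goes through the full dynamic program.
    """
    seq = consensus.sequence
    ref = assay.amplicon_seq
    if seq == ref:
        return AlignedConsensus(consensus, assay.assay_id, (0, len(ref)), [], [], 1.0)
    if len(seq) == len(ref):
        diffs = [i for i, (a, b) in enumerate(zip(seq, ref)) if a != b]
        if len(diffs) <= 2:
            events = [Event("SNV", i, ref[i], seq[i]) for i in diffs if seq[i] != "N"]
            npos = [i for i in diffs if seq[i] == "N"]
            ident = (len(ref) - len(events)) / len(ref)
            return AlignedConsensus(consensus, assay.assay_id, (0, len(ref)), events, npos, ident)
    score, path = align_affine(seq, ref)
    if not path:
        return None
    matches = sum(1 for op, qp, rp in path if op == "M" and seq[qp] == ref[rp])
    identity = matches / len(path)
    if identity < MIN_ALIGN_IDENTITY:
        return None
    events, npos = _events_from_path(seq, ref, path)
    ref_positions = [rp for op, _, rp in path if op in ("M", "D")]
    span = (min(ref_positions), max(ref_positions) + 1) if ref_positions else (0, 0)
    return AlignedConsensus(consensus, assay.assay_id, span, events, npos, identity)


def flag_spikeins(alignments: Iterable[AlignedConsensus], assay: Assay) -> None:
    """Mark alignments carrying the assay's diagnostic ATG insertion."""
    sig_pos, sig_ins = spikein_signature(assay)
    for a in alignments:
        for e in a.events:
            if e.kind == "INS" and e.pos == sig_pos and e.alt == sig_ins:
                a.is_spikein = True
                break


def count_spikein(alignments: Iterable[AlignedConsensus], assay: Assay, spikein: SpikeInControl) -> int:
    """Consensus reads whose alignment contains the spike-in's ATG insertion."""
    flag_spikeins(alignments, assay)
    return sum(1 for a in alignments if a.is_spikein)


# ---------------------------------------------------------------------------
# pileup


@dataclass
class Pileup:
    assay_id: str
    length: int
    depth: np.ndarray  # consensus spanning each position, N-excluded
    subs: Counter  # (pos, alt base) -> count
    ins: Counter  # (pos, inserted seq) -> count
    dels: Counter  # (pos, deleted ref) -> count
    del_cover: np.ndarray  # consensus with a deletion spanning each position
    n_consensus: int

    def base_counts(self, pos: int, ref_base: str) -> dict[str, int]:
        counts = {b: 0 for b in "ACGT"}
        for (p, alt), c in self.subs.items():
            if p == pos:
                counts[alt] += c
        counts[ref_base] += int(self.depth[pos]) - sum(counts.values()) - int(self.del_cover[pos])
        return counts


def build_pileup(alignments: Sequence[AlignedConsensus], assay: Assay) -> Pileup:
    """Aggregate events per amplicon position; spike-in consensuses are excluded."""
    L = len(assay.amplicon_seq)
    delta = np.zeros(L + 1, dtype=np.int64)
    n_excl = np.zeros(L, dtype=np.int64)
    del_delta = np.zeros(L + 1, dtype=np.int64)
    subs: Counter = Counter()
    ins: Counter = Counter()
    dels: Counter = Counter()
    n_consensus = 0
    for a in alignments:
        if a.is_spikein:
            continue
        n_consensus += 1
        j0, j1 = a.ref_span
        delta[j0] += 1
        delta[j1] -= 1
        for p in a.n_positions:
            n_excl[p] += 1
        for e in a.events:
            if e.kind == "SNV":
                subs[(e.pos, e.alt)] += 1
            elif e.kind == "INS":
                ins[(e.pos, e.alt)] += 1
            else:
                dels[(e.pos, e.ref)] += 1
                del_delta[e.pos] += 1
                del_delta[e.pos + len(e.ref)] -= 1
    depth = np.cumsum(delta[:-1]) - n_excl
    del_cover = np.cumsum(del_delta[:-1])
    return Pileup(assay.assay_id, L, depth, subs, ins, dels, del_cover, n_consensus)


# ---------------------------------------------------------------------------
# calling


@dataclass
class VariantCall:
    variant: TargetVariant
    n_mut: int
    n_total: int
    maf: float  # percent
    status: str  # called | provisional | rescued | absent
    flags: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key

    @property
    def detected(self) -> bool:
        return self.status in ("called", "rescued")


@dataclass
class SampleResult:
    sample_id: str
    patient_id: str
    timepoint: str
    molecule_count: int  # consensus reads covering the tumor-specific locus
    calls: list[VariantCall]
    classification: str = "negative"  # positive | negative | negative_low_input
    qc_flags: set[str] = field(default_factory=set)
    run: str = "run1"
    stats: dict = field(default_factory=dict)

    def call_for(self, key: tuple[str, int, str, str]) -> VariantCall | None:
        for c in self.calls:
            if c.key == key:
                return c
        return None


def _status_for(vclass: str, n_mut: int, snv_min: int, indel_min: int) -> str:
    if n_mut == 0:
        return "absent"
    if vclass == "SNV":
        return "called" if n_mut >= snv_min else "provisional"
    return "called" if n_mut >= indel_min else "provisional"


def call_sample_variants(
    pileup: Pileup,
    targets: Sequence[TargetVariant],
    assay: Assay,
    snv_min: int = SNV_MIN_READS,
    indel_min: int = INDEL_MIN_READS,
    report_all_events: bool = False,
) -> list[VariantCall]:
    """Apply the calling thresholds to every target and every observed
    non-target event inside the assay's target window.

    Observed events outside any target are reported with label
    ``novel``; they never drive sample positivity but surface for
    review (replacing by-hand inspection of the alignments).
    """
    calls: list[VariantCall] = []
    target_keys = set()
    lo, hi = assay.target_window

    def make_call(variant: TargetVariant, n_mut: int) -> VariantCall:
        n_total = int(pileup.depth[variant.pos]) if variant.pos < pileup.length else 0
        flags = set()
        if n_total == 0:
            flags.add("no_coverage")
            status = "absent"
            maf = 0.0
        else:
            status = _status_for(variant.vclass, n_mut, snv_min, indel_min)
            maf = 100.0 * n_mut / n_total
        return VariantCall(variant, n_mut, n_total, maf, status, flags)

    for t in targets:
        target_keys.add(t.key)
        if t.vclass == "SNV":
            n_mut = pileup.subs.get((t.pos, t.alt), 0)
        elif t.vclass == "INS":
            n_mut = pileup.ins.get((t.pos, t.alt), 0)
        elif t.vclass == "DEL":
            n_mut = pileup.dels.get((t.pos, t.ref), 0)
        else:  # DELINS: not produced by the aligner's event model
            n_mut = 0
        calls.append(make_call(t, n_mut))

    observed: list[tuple[str, int, str, str, int]] = []
    for (p, alt), c in sorted(pileup.subs.items()):
        observed.append(("SNV", p, assay.amplicon_seq[p], alt, c))
    for (p, alt), c in sorted(pileup.ins.items()):
        observed.append(("INS", p, "", alt, c))
    for (p, ref), c in sorted(pileup.dels.items()):
        observed.append(("DEL", p, ref, "", c))
    for vclass, p, ref, alt, c in observed:
        if (pileup.assay_id, p, ref, alt) in target_keys:
            continue
        if not report_all_events and not (lo <= p < hi):
            continue
        novel = TargetVariant(pileup.assay_id, p, ref, alt, vclass, "novel")
        calls.append(make_call(novel, c))
    return calls


def rescue_provisional(
    patient_samples: Sequence[SampleResult],
    rescue_anchor: int = RESCUE_ANCHOR_READS,
    low_input: int = LOW_INPUT_MOLECULES,
) -> list[SampleResult]:
    """Cross-sample rescue within one patient, then (re)classification.

    A provisional SNV in sample S becomes *rescued* iff another sample
    of the same patient shows the identical normalized variant with at
    least ``rescue_anchor`` consensus reads.
    """
    by_patient: dict[str, list[SampleResult]] = {}
    for s in patient_samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    for samples in by_patient.values():
        for s in samples:
            for call in s.calls:
                if call.status != "provisional" or call.variant.vclass != "SNV":
                    continue
                for other in samples:
                    if other is s:
                        continue
                    anchor = other.call_for(call.key)
                    if anchor is not None and anchor.n_mut >= rescue_anchor:
                        call.status = "rescued"
                        break
    out = list(patient_samples)
    for s in out:
        s.classification = classify_sample(s.calls, s.molecule_count, low_input)
    return out


def classify_sample(
    calls: Sequence[VariantCall],
    molecule_count: int,
    low_input: int = LOW_INPUT_MOLECULES,
) -> str:
    """ctDNA classification: positive / negative / negative_low_input.

    Only tumor-specific and resistance variants drive positivity;
    variants labeled ``secondary`` (or novel events) never do.
    """
    for c in calls:
        if c.variant.label in POSITIVITY_LABELS and c.detected:
            return "positive"
    if molecule_count < low_input:
        return "negative_low_input"
    return "negative"


# ---------------------------------------------------------------------------
# VCF / TSV export


def write_vcf(sample: SampleResult, panel: PatientPanel, path: str | Path) -> None:
    """Minimal VCF 4.2 with amplicons as contigs and 1-based positions.

    Indels are re-padded with the preceding amplicon base per the VCF
    convention; calls with status ``absent`` are not emitted.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=umicall (panel {panel.patient_id})",
        f"##umicall_thresholds=snv_min={SNV_MIN_READS},indel_min={INDEL_MIN_READS},rescue_anchor={RESCUE_ANCHOR_READS}",
    ]
    for a in panel.assays:
        lines.append(f"##contig=<ID={a.assay_id},length={len(a.amplicon_seq)}>")
    lines += [
        '##INFO=<ID=NMUT,Number=1,Type=Integer,Description="Mutant consensus reads">',
        '##INFO=<ID=NTOT,Number=1,Type=Integer,Description="Total consensus reads at locus">',
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Mutant allele frequency, percent">',
        '##INFO=<ID=STATUS,Number=1,Type=String,Description="called, provisional or rescued">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in sample.calls:
        if c.status == "absent":
            continue
        v = c.variant
        amplicon = panel.assay(v.assay_id).amplicon_seq
        if v.vclass == "SNV":
            pos1, ref, alt = v.pos + 1, v.ref, v.alt
        else:
            if v.pos == 0:
                raise ValueError("cannot anchor an indel at amplicon position 0 for VCF export")
            anchor = amplicon[v.pos - 1]
            pos1, ref, alt = v.pos, anchor + v.ref, anchor + v.alt
        vid = v.name.replace(" ", "_") if v.name else "."
        info = f"NMUT={c.n_mut};NTOT={c.n_total};MAF={c.maf:.4f};STATUS={c.status}"
        lines.append(f"{v.assay_id}\t{pos1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def sample_calls_table(sample: SampleResult):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": sample.sample_id,
                "patient_id": sample.patient_id,
                "timepoint": sample.timepoint,
                "assay_id": c.variant.assay_id,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "vclass": c.variant.vclass,
                "label": c.variant.label,
                "n_mut": c.n_mut,
                "n_total": c.n_total,
                "maf_percent": round(c.maf, 6),
                "status": c.status,
            }
            for c in sample.calls
        ]
    )
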