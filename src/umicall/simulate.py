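"""Synthetic UMI-tagged amplicon library and qPCR simulator.

Emulates the statistical structure of a barcoded amplicon (SiMSen-Seq
style) library: input cfDNA molecules are drawn per assay, each molecule
receives a random unique molecular identifier (UMI), is amplified into a
read family whose size follows a zero-truncated negative binomial, and
every read acquires i.i.d. per-base substitution/indel errors outside
the UMI.  A ground-truth manifest records every molecule, so downstream
consensus and calling can be audited exactly.

Reads are laid out as ``[UMI][fwd primer][insert][rev-primer segment]``
with adapters assumed pre-trimmed.  Mutant molecule counts are drawn
Binomial(n, MAF) per target variant; spike-in molecule counts are taken
verbatim from the spec (they model a pipetted control, not a sampled
one).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .panel import PatientPanel, TargetVariant, apply_variant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i

#: qPCR standard-curve input quantities: threefold dilutions from 10 ng down to 0.37 ng.
STANDARD_QUANTITIES_NG = (10.0, 10.0 / 3.0, 10.0 / 9.0, 10.0 / 27.0)


@dataclass
class SimSpec:
    """Study conditions for one simulated plasma sample.

    ``molecules`` maps assay_id to input cfDNA molecule count (an int
    applies to every assay).  ``maf`` maps a target-variant name or its
    assay_id to the mutant allele fraction in [0, 1].  ``spikein`` maps
    assay_id to the exact number of spike-in control molecules added.
    Family sizes follow a zero-truncated negative binomial with mean
    ``family_mean`` and dispersion ``family_dispersion`` (``family_dist
    = "fixed"`` gives constant families, handy for controlled tests).
    """

    molecules: int | Mapping[str, int] = 1000
    maf: Mapping[str, float] = field(default_factory=dict)
    spikein: Mapping[str, int] = field(default_factory=dict)
    umi_length: int = 12
    family_dist: str = "ztnb"
    family_mean: float = 20.0
    family_dispersion: float = 2.0
    e_sub: float = 0.001
    e_indel: float = 1e-4
    umi_error_rate: float = 0.0
    read_quality: str = "I"  # constant Phred+33 symbol
    seed: int = 0

    def molecules_for(self, assay_id: str) -> int:
        if isinstance(self.molecules, Mapping):
            return int(self.molecules.get(assay_id, 0))
        return int(self.molecules)

    def maf_for(self, variant: TargetVariant) -> float:
        if variant.name and variant.name in self.maf:
            return float(self.maf[variant.name])
        return float(self.maf.get(variant.assay_id, 0.0))

    def validate(self) -> None:
        if isinstance(self.molecules, Mapping):
            counts = list(self.molecules.values())
        else:
            counts = [self.molecules]
        if any(c < 0 for c in counts):
            raise ValueError("molecule counts must be >= 0")
        if any(not (0.0 <= m <= 1.0) for m in self.maf.values()):
            raise ValueError("MAF values must lie in [0, 1]")
        for name, rate in (("e_sub", self.e_sub), ("e_indel", self.e_indel)):
            if not (0.0 <= rate <= 0.1):
                raise ValueError(f"{name} must lie in [0, 0.1]")
        if self.family_mean < 1:
            raise ValueError("family_mean must be >= 1")
        if self.family_dist not in ("ztnb", "fixed"):
            raise ValueError(f"unknown family-size distribution {self.family_dist!r}")


@dataclass
class TruthManifest:
    """Ground truth for one simulated sample: one row per input molecule."""

    molecules: pd.DataFrame  # assay_id, molecule_id, umi, is_mutant, is_spikein, variant, family_size, true_sequence
    realized_maf: dict[str, float]  # variant name -> realized mutant fraction
    mutant_counts: dict[str, int]
    total_molecules: int
    spikein_counts: dict[str, int]
    seed: int

    @property
    def n_reads(self) -> int:
        return int(self.molecules["family_size"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.molecules.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# family-size distribution


def _ztnb_raw_mean(mu: float, k: float) -> float:
    """Raw NB mean m such that the zero-truncated mean equals mu."""
    m = mu
    for _ in range(60):
        p0 = (k / (k + m)) ** k
        m_new = mu * (1.0 - p0)
        if abs(m_new - m) < 1e-12:
            break
        m = m_new
    return m


def draw_family_sizes(rng: np.random.Generator, n: int, spec: SimSpec) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if spec.family_dist == "fixed":
        return np.full(n, int(round(spec.family_mean)), dtype=np.int64)
    k = spec.family_dispersion
    m = _ztnb_raw_mean(spec.family_mean, k)
    p = k / (k + m)
    sizes = rng.negative_binomial(k, p, n)
    zeros = sizes == 0
    while zeros.any():  # rejection-resample zeros -> zero-truncated NB
        sizes[zeros] = rng.negative_binomial(k, p, int(zeros.sum()))
        zeros = sizes == 0
    return sizes.astype(np.int64)


# ---------------------------------------------------------------------------
# error injection


def _mutate_reads(rng: np.random.Generator, seq: str, n_reads: int, spec: SimSpec) -> list[str]:
    """Return n_reads copies of seq with i.i.d. substitution and indel errors."""
    L = len(seq)
    if n_reads == 0:
        return []
    mat = np.tile(np.frombuffer(seq.encode(), dtype=np.uint8), (n_reads, 1))
    # substitutions: per-read error counts, vectorized for the 1-error bulk
    k_sub = rng.binomial(L, spec.e_sub, n_reads)
    one = np.nonzero(k_sub == 1)[0]
    if one.size:
        cols = rng.integers(0, L, one.size)
        cur = _CODE_OF[mat[one, cols]]
        mat[one, cols] = _BASES[(cur + rng.integers(1, 4, one.size)) % 4]
    for r in np.nonzero(k_sub >= 2)[0]:
        cols = rng.choice(L, int(k_sub[r]), replace=False)
        cur = _CODE_OF[mat[r, cols]]
        mat[r, cols] = _BASES[(cur + rng.integers(1, 4, cols.size)) % 4]
    raw = mat.tobytes()
    reads = [raw[i * L:(i + 1) * L].decode() for i in range(n_reads)]
    # indel errors: rare, handled per read on strings
    if spec.e_indel > 0:
        k_ind = rng.binomial(L, spec.e_indel, n_reads)
        for r in np.nonzero(k_ind)[0]:
            s = reads[r]
            for _ in range(int(k_ind[r])):
                p = int(rng.integers(0, len(s)))
                if rng.random() < 0.5 and len(s) > 1:
                    s = s[:p] + s[p + 1:]  # 1-base deletion
                else:
                    b = "ACGT"[int(rng.integers(0, 4))]
                    s = s[:p] + b + s[p:]  # 1-base insertion
            reads[r] = s
    return reads


def _draw_umis(rng: np.random.Generator, n: int, umi_length: int, umi_error_rate: float) -> list[str]:
    codes = rng.integers(0, 4, (n, umi_length))
    raw = _BASES[codes].tobytes()
    umis = [raw[i * umi_length:(i + 1) * umi_length].decode() for i in range(n)]
    return umis


# ---------------------------------------------------------------------------
# sample simulation


def simulate_sample(panel: PatientPanel, spec: SimSpec) -> tuple[list[tuple[str, str]], TruthManifest]:
    """Simulate one sample; returns ``(reads, manifest)``.

    ``reads`` is a list of (name, sequence) in deterministic order;
    sequence = UMI + errored molecule copy.  The manifest has one row
    per input molecule with its realized family size.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []  # manifest rows
    reads: list[tuple[str, str]] = []
    mutant_counts: dict[str, int] = {}
    realized_maf: dict[str, float] = {}
    spikein_counts: dict[str, int] = {}
    total = 0
    mol_id = 0

    for assay in panel.assays:
        n = spec.molecules_for(assay.assay_id)
        variants = [v for v in panel.variants_for(assay.assay_id)]
        mafs = np.array([spec.maf_for(v) for v in variants], dtype=float)
        if mafs.sum() > 1.0:
            raise ValueError(f"MAFs for assay {assay.assay_id} sum to more than 1")
        # molecule category counts: one multinomial draw over (variants..., wild-type)
        if n > 0:
            probs = np.append(mafs, 1.0 - mafs.sum())
            counts = rng.multinomial(n, probs)
        else:
            counts = np.zeros(len(variants) + 1, dtype=np.int64)
        n_spike = int(spec.spikein.get(assay.assay_id, 0))
        spike = panel.spikein_for(assay.assay_id)
        if n_spike > 0 and spike is None:
            raise ValueError(f"spike-in molecules requested for assay {assay.assay_id} without a spike-in definition")

        groups: list[tuple[str, bool, bool, str]] = []  # (sequence, is_mutant, is_spikein, variant name)
        group_sizes: list[int] = []
        for v, c in zip(variants, counts[:-1]):
            groups.append((apply_variant(assay.amplicon_seq, v), True, False, v.name or v.assay_id))
            group_sizes.append(int(c))
            key = v.name or v.assay_id
            mutant_counts[key] = mutant_counts.get(key, 0) + int(c)
            realized_maf[key] = (int(c) / n) if n else 0.0
        groups.append((assay.amplicon_seq, False, False, ""))
        group_sizes.append(int(counts[-1]))
        if n_spike > 0:
            groups.append((spike.sequence, False, True, ""))
            group_sizes.append(n_spike)
        spikein_counts[assay.assay_id] = n_spike
        total += n + n_spike

        for (mseq, is_mut, is_spk, vname), n_mol in zip(groups, group_sizes):
            if n_mol == 0:
                continue
            fam = draw_family_sizes(rng, n_mol, spec)
            umis = _draw_umis(rng, n_mol, spec.umi_length, spec.umi_error_rate)
            n_reads = int(fam.sum())
            inserts = _mutate_reads(rng, mseq, n_reads, spec)
            # optional UMI errors (default off): substitutions inside the tag
            umi_reads: list[str] = []
            for i in range(n_mol):
                umi_reads.extend([umis[i]] * int(fam[i]))
            if spec.umi_error_rate > 0:
                k_err = rng.binomial(spec.umi_length, spec.umi_error_rate, n_reads)
                for r in np.nonzero(k_err)[0]:
                    u = list(umi_reads[r])
                    for p in rng.choice(spec.umi_length, int(k_err[r]), replace=False):
                        u[p] = "ACGT"[(_CODE_OF[ord(u[p])] + int(rng.integers(1, 4))) % 4]
                    umi_reads[r] = "".join(u)
            ridx = 0
            for i in range(n_mol):
                rows.append((assay.assay_id, mol_id, umis[i], is_mut, is_spk, vname, int(fam[i]), mseq))
                for j in range(int(fam[i])):
                    reads.append((f"m{mol_id}_r{j}", umi_reads[ridx] + inserts[ridx]))
                    ridx += 1
                mol_id += 1

    manifest = TruthManifest(
        molecules=pd.DataFrame(
            rows,
            columns=["assay_id", "molecule_id", "umi", "is_mutant", "is_spikein", "variant", "family_size", "true_sequence"],
        ),
        realized_maf=realized_maf,
        mutant_counts=mutant_counts,
        total_molecules=total,
        spikein_counts=spikein_counts,
        seed=spec.seed,
    )
    return reads, manifest


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: str = "I") -> int:
    """Write 4-line FASTQ records with a constant Phred+33 quality symbol."""
    n = 0
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality * len(seq)}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Minimal 4-line FASTQ reader returning (name, sequence) pairs."""
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header.strip().lstrip("@"), seq))
    return out


# ---------------------------------------------------------------------------
# qPCR simulation


@dataclass
class QpcrSim:
    """Simulated qPCR readout for the QC battery."""

    standard_points: list[tuple[float, float]]  # (quantity ng, Cq)
    short_qty: float
    long_qty: float
    cq_inhibition_control: float
    cq_reference: float
    inhibition_shift: float
    slope: float
    intercept: float

    def to_frame(self) -> pd.DataFrame:
        rows = [("standard", q, cq) for q, cq in self.standard_points]
        rows.append(("short", self.short_qty, self.intercept + self.slope * math.log10(self.short_qty) if self.short_qty > 0 else float("nan")))
        rows.append(("long", self.long_qty, self.intercept + self.slope * math.log10(self.long_qty) if self.long_qty > 0 else float("nan")))
        rows.append(("inhibition_control", float("nan"), self.cq_inhibition_control))
        rows.append(("reference", float("nan"), self.cq_reference))
        return pd.DataFrame(rows, columns=["assay_type", "quantity", "cq"])


def simulate_qpcr(
    spec: SimSpec,
    contamination_fraction: float,
    inhibition_shift: float,
    cfdna_ng: float = 5.0,
    efficiency: float = 1.0,
    intercept: float = 24.0,
    noise_sd: float = 0.05,
) -> QpcrSim:
    """Simulate the qPCR quality-control readout for one sample.

    Standard-curve points are generated at threefold dilutions from 10
    down to 0.37 ng with ``Cq = intercept + slope * log10(q)`` plus
    Gaussian noise; the long-amplicon (cellular DNA surrogate) quantity
    is ``contamination_fraction`` times the short-amplicon quantity, and
    the inhibition control Cq sits ``inhibition_shift`` cycles above the
    reference.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0 (configuration error)")
    if not (0.0 <= contamination_fraction <= 1.0):
        raise ValueError("contamination_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed + 777)
    slope = -1.0 / math.log10(1.0 + efficiency)
    pts = [
        (q, intercept + slope * math.log10(q) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0))
        for q in STANDARD_QUANTITIES_NG
    ]
    cq_ref = intercept + slope * math.log10(cfdna_ng)
    cq_inh = cq_ref + inhibition_shift + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
    return QpcrSim(
        standard_points=pts,
        short_qty=cfdna_ng,
        long_qty=contamination_fraction * cfdna_ng,
        cq_inhibition_control=cq_inh,
        cq_reference=cq_ref,
        inhibition_shift=inhibition_shift,
        slope=slope,
        intercept=intercept,
    )
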