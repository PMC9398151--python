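"""Patient-specific amplicon panel model.

A panel is the unit everything downstream aligns against: five short
amplicons (65-99 bp) per patient -- one carrying the patient's
tumor-specific mutation and four shared assays covering tyrosine kinase
inhibitor (TKI) resistance hotspots in KIT and PDGFRA -- plus synthetic
spike-in control sequences used to detect library-construction failure.

Coordinates are 0-based, half-open, on the amplicon top strand.  Indels
are stored left-normalized with an empty ``ref`` (insertion) or empty
``alt`` (deletion); VCF export re-pads them with the preceding base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMPLICON_MIN_LEN = 65
AMPLICON_MAX_LEN = 99
ASSAYS_PER_PANEL = 5
DNA_ALPHABET = frozenset("ACGT")

VARIANT_CLASSES = ("SNV", "INS", "DEL", "DELINS")
VARIANT_LABELS = ("tumor_specific", "resistance", "secondary")


class PanelConfigError(ValueError):
    """Raised when a panel file does not match the expected schema."""


class PanelValidationError(ValueError):
    """Raised when a structurally parseable panel violates panel invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("panel validation failed:\n  " + "\n  ".join(self.violations))


@dataclass(frozen=True)
class Assay:
    """One short amplicon with its primers and expected-variant window."""

    assay_id: str
    gene: str
    exon: str
    amplicon_seq: str
    fwd_primer: str
    rev_primer: str  # top-strand segment at the amplicon's 3' end
    target_window: tuple[int, int]  # 0-based half-open, between the primers

    def __len__(self) -> int:
        return len(self.amplicon_seq)


@dataclass(frozen=True)
class TargetVariant:
    """A variant expected on one assay, in amplicon coordinates.

    ``ref == ""`` encodes a pure insertion and ``alt == ""`` a pure
    deletion; both are kept left-normalized so that variant identity is
    exact tuple equality (required by the cross-sample rescue rule).
    """

    assay_id: str
    pos: int
    ref: str
    alt: str
    vclass: str
    label: str
    name: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.assay_id, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.vclass in ("INS", "DEL", "DELINS")


@dataclass(frozen=True)
class SpikeInControl:
    """Synthetic control: the amplicon with ATG inserted after the forward primer."""

    assay_id: str
    sequence: str
    expected_count: int


@dataclass
class PatientPanel:
    patient_id: str
    assays: list[Assay]
    variants: list[TargetVariant]
    spikeins: list[SpikeInControl] = field(default_factory=list)

    @property
    def tumor_variant(self) -> TargetVariant:
        return next(v for v in self.variants if v.label == "tumor_specific")

    @property
    def tumor_assay(self) -> Assay:
        return self.assay(self.tumor_variant.assay_id)

    def assay(self, assay_id: str) -> Assay:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(assay_id)

    def variants_for(self, assay_id: str) -> list[TargetVariant]:
        return [v for v in self.variants if v.assay_id == assay_id]

    def spikein_for(self, assay_id: str) -> SpikeInControl | None:
        for s in self.spikeins:
            if s.assay_id == assay_id:
                return s
        return None


# ---------------------------------------------------------------------------
# indel normalization


def left_normalize_indel(amplicon: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align a pure insertion or deletion within the amplicon.

    The inserted/deleted string is rotated leftwards while the base
    preceding the event equals its last base, the standard repeat-aware
    normalization.  SNVs and delins pass through unchanged.
    """
    if ref and alt:  # SNV or delins: nothing to shift
        return pos, ref, alt
    moving = ref or alt
    if not moving:
        return pos, ref, alt
    while pos > 0 and amplicon[pos - 1] == moving[-1]:
        moving = amplicon[pos - 1] + moving[:-1]
        pos -= 1
    return (pos, moving, "") if ref else (pos, "", moving)


def apply_variant(amplicon: str, variant: TargetVariant) -> str:
    """Return the amplicon sequence carrying the variant allele."""
    p = variant.pos
    return amplicon[:p] + variant.alt + amplicon[p + len(variant.ref):]


# ---------------------------------------------------------------------------
# validation


def validate_assay(assay: Assay) -> list[str]:
    """Check all assay invariants; return human-readable, machine-coded violations."""
    v: list[str] = []
    seq = assay.amplicon_seq
    if not set(seq) <= DNA_ALPHABET:
        v.append(f"amplicon_not_acgt: {assay.assay_id} amplicon contains non-ACGT characters")
    if len(seq) < AMPLICON_MIN_LEN:
        v.append(
            f"amplicon_length_below_min: {assay.assay_id} amplicon length "
            f"{len(seq)} out of {AMPLICON_MIN_LEN}–{AMPLICON_MAX_LEN} range"
        )
    if len(seq) > AMPLICON_MAX_LEN:
        v.append(
            f"amplicon_length_above_max: {assay.assay_id} amplicon length "
            f"{len(seq)} out of {AMPLICON_MIN_LEN}–{AMPLICON_MAX_LEN} range"
        )
    if not seq.startswith(assay.fwd_primer):
        v.append(f"fwd_primer_not_prefix: {assay.assay_id} forward primer is not a prefix of the amplicon")
    if not seq.endswith(assay.rev_primer):
        v.append(f"rev_primer_not_suffix: {assay.assay_id} reverse-primer segment is not a suffix of the amplicon")
    lo, hi = assay.target_window
    if not (len(assay.fwd_primer) <= lo < hi <= len(seq) - len(assay.rev_primer)):
        v.append(f"target_window_invalid: {assay.assay_id} window {assay.target_window} not strictly between primers")
    return v


def validate_panel(panel: PatientPanel) -> list[str]:
    v: list[str] = []
    if len(panel.assays) != ASSAYS_PER_PANEL:
        v.append(f"expected_five_assays: expected five assays, got {len(panel.assays)}")
    for a in panel.assays:
        v.extend(validate_assay(a))
    assay_ids = {a.assay_id for a in panel.assays}
    tumor = [x for x in panel.variants if x.label == "tumor_specific"]
    if len(tumor) != 1:
        v.append(f"expected_one_tumor_variant: expected exactly one tumor-specific variant, got {len(tumor)}")
    for var in panel.variants:
        if var.assay_id not in assay_ids:
            v.append(f"variant_unknown_assay: variant at {var.pos} references unknown assay {var.assay_id}")
            continue
        assay = panel.assay(var.assay_id)
        if var.vclass not in VARIANT_CLASSES:
            v.append(f"variant_class_invalid: {var.assay_id}:{var.pos} class {var.vclass!r}")
        if var.label not in VARIANT_LABELS:
            v.append(f"variant_label_invalid: {var.assay_id}:{var.pos} label {var.label!r}")
        if var.vclass == "SNV" and not (len(var.ref) == 1 and len(var.alt) == 1):
            v.append(f"snv_shape_invalid: {var.assay_id}:{var.pos} SNV must have single-base ref and alt")
        if var.vclass == "INS" and var.ref != "":
            v.append(f"ins_shape_invalid: {var.assay_id}:{var.pos} insertion must have empty ref")
        if var.vclass == "DEL" and var.alt != "":
            v.append(f"del_shape_invalid: {var.assay_id}:{var.pos} deletion must have empty alt")
        lo, hi = assay.target_window
        if not (lo <= var.pos < hi):
            v.append(f"variant_outside_window: {var.assay_id}:{var.pos} outside target window {assay.target_window}")
        if var.ref and assay.amplicon_seq[var.pos: var.pos + len(var.ref)] != var.ref:
            v.append(f"variant_ref_mismatch: {var.assay_id}:{var.pos} ref {var.ref!r} does not match amplicon")
        npos, nref, nalt = left_normalize_indel(assay.amplicon_seq, var.pos, var.ref, var.alt)
        if (npos, nref, nalt) != (var.pos, var.ref, var.alt):
            v.append(f"variant_not_left_normalized: {var.assay_id}:{var.pos} normalizes to position {npos}")
    for s in panel.spikeins:
        if s.assay_id not in assay_ids:
            v.append(f"spikein_unknown_assay: spike-in references unknown assay {s.assay_id}")
            continue
        assay = panel.assay(s.assay_id)
        if s.sequence != make_spikein_sequence(assay):
            v.append(f"spikein_sequence_invalid: {s.assay_id} spike-in is not the amplicon with an ATG insertion after the forward primer")
        if s.expected_count < 0:
            v.append(f"spikein_count_negative: {s.assay_id}")
    return v


def make_spikein_sequence(assay: Assay) -> str:
    """Amplicon with the diagnostic ATG trinucleotide inserted right after the forward primer."""
    k = len(assay.fwd_primer)
    return assay.amplicon_seq[:k] + "ATG" + assay.amplicon_seq[k:]


def spikein_signature(assay: Assay) -> tuple[int, str]:
    """Left-normalized (position, inserted-sequence) identity of the spike-in insertion."""
    pos, _, ins = left_normalize_indel(assay.amplicon_seq, len(assay.fwd_primer), "", "ATG")
    return pos, ins


# ---------------------------------------------------------------------------
# panel file I/O (YAML)

_VCLASS_FOR_SHAPE = {
    (True, True): "SNV",
    (False, True): "INS",
    (True, False): "DEL",
}


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise PanelConfigError(f"configuration error: missing field {key!r} in {context}")
    return mapping[key]


def _variant_from_dict(d: dict, i: int) -> TargetVariant:
    ctx = f"variants[{i}]"
    ref = str(_require(d, "ref", ctx) or "").upper()
    alt = str(_require(d, "alt", ctx) or "").upper()
    vclass = d.get("vclass")
    if vclass is None:
        if ref and alt:
            vclass = "SNV" if len(ref) == len(alt) == 1 else "DELINS"
        else:
            vclass = _VCLASS_FOR_SHAPE[(bool(ref), bool(alt))]
    return TargetVariant(
        assay_id=str(_require(d, "assay_id", ctx)),
        pos=int(_require(d, "pos", ctx)),
        ref=ref,
        alt=alt,
        vclass=str(vclass),
        label=str(_require(d, "label", ctx)),
        name=str(d.get("name", "")),
    )


def load_panel(path: str | Path) -> PatientPanel:
    """Load and validate a panel definition file.

    Raises :class:`PanelConfigError` on schema problems and
    :class:`PanelValidationError` (listing every violation) when the
    parsed panel breaks an invariant.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise PanelConfigError(f"configuration error: cannot parse {path}: {e}") from e
    if not isinstance(doc, dict):
        raise PanelConfigError("configuration error: panel document must be a mapping")
    patient_id = str(_require(doc, "patient_id", "panel"))
    assays_raw = _require(doc, "assays", "panel")
    variants_raw = _require(doc, "variants", "panel")
    if not isinstance(assays_raw, list) or not isinstance(variants_raw, list):
        raise PanelConfigError("configuration error: 'assays' and 'variants' must be lists")
    assays = []
    for i, a in enumerate(assays_raw):
        ctx = f"assays[{i}]"
        window = _require(a, "target_window", ctx)
        assays.append(
            Assay(
                assay_id=str(_require(a, "assay_id", ctx)),
                gene=str(_require(a, "gene", ctx)),
                exon=str(_require(a, "exon", ctx)),
                amplicon_seq=str(_require(a, "amplicon_seq", ctx)).upper(),
                fwd_primer=str(_require(a, "fwd_primer", ctx)).upper(),
                rev_primer=str(_require(a, "rev_primer", ctx)).upper(),
                target_window=(int(window[0]), int(window[1])),
            )
        )
    variants = [_variant_from_dict(d, i) for i, d in enumerate(variants_raw)]
    spikeins = [
        SpikeInControl(
            assay_id=str(_require(s, "assay_id", f"spikeins[{i}]")),
            sequence=str(_require(s, "sequence", f"spikeins[{i}]")).upper(),
            expected_count=int(_require(s, "expected_count", f"spikeins[{i}]")),
        )
        for i, s in enumerate(doc.get("spikeins", []) or [])
    ]
    panel = PatientPanel(patient_id=patient_id, assays=assays, variants=variants, spikeins=spikeins)
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(violations)
    return panel


def write_panel(panel: PatientPanel, path: str | Path) -> None:
    doc = {
        "patient_id": panel.patient_id,
        "assays": [
            {
                "assay_id": a.assay_id,
                "gene": a.gene,
                "exon": a.exon,
                "amplicon_seq": a.amplicon_seq,
                "fwd_primer": a.fwd_primer,
                "rev_primer": a.rev_primer,
                "target_window": [a.target_window[0], a.target_window[1]],
            }
            for a in panel.assays
        ],
        "variants": [
            {
                "assay_id": v.assay_id,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.vclass,
                "label": v.label,
                "name": v.name,
            }
            for v in panel.variants
        ],
        "spikeins": [
            {"assay_id": s.assay_id, "sequence": s.sequence, "expected_count": s.expected_count}
            for s in panel.spikeins
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def export_references_fasta(panel: PatientPanel, path: str | Path) -> None:
    """Write amplicon references and spike-in sequences for inspection."""
    records = [
        SeqRecord(Seq(a.amplicon_seq), id=a.assay_id, description=f"{a.gene} exon {a.exon} amplicon")
        for a in panel.assays
    ]
    records += [
        SeqRecord(Seq(s.sequence), id=f"{s.assay_id}_spikein", description="spike-in control (ATG insertion)")
        for s in panel.spikeins
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# packaged demonstration panel (invented but structurally valid sequences)

_DEMO_ASSAYS = [
    # (assay_id, gene, exon, amplicon, fwd_len, rev_len)
    ("KIT_11", "KIT", "11", "TAGCTTAAAGCTCACCCTGAGCTGAACTCTGCCTTTATTGCGGTGGTCGCTACCAACCCGTACACGACGCACAAATTAACAACTG", 20, 20),
    ("KIT_13", "KIT", "13", "GTCTTTAACGATCGGAACTCGATGATGGAGCATAGTTTACCAAGACCCGACCAGCGCGCAGGTCAAGATAAGATGTAC", 20, 20),
    ("KIT_14", "KIT", "14", "TTGAAAGCGGGACGCCGCACTTTAAATTTCCGACCACGCCGTTATCATATGGAACCTAGGCCTCCCATCTAT", 20, 20),
    ("KIT_17", "KIT", "17", "GTGAGTGGAGACATCGTCTGCCAGCTGCGCGCTGTACGCCGGGATTCCGTGGATGTTAGTTTCGGGCCAAAGAATCGCGAATTCAAGTAG", 20, 20),
    ("PDGFRA_18", "PDGFRA", "18", "ATAGCTGAATTCCGTGCGAATCTAGGTCGTTGCGTACACCGCCCTCCAGTCAGCTAGCGGACGGGATAATTTCATCATCAGT", 20, 20),
]

_OTHER_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}


def demo_panel(patient_id: str = "P01", spikein_count: int = 50) -> PatientPanel:
    """A schematically realistic five-assay panel with invented sequences.

    One KIT exon 11 six-base deletion stands in for the patient's
    tumor-specific mutation; the four shared assays each carry a
    resistance-hotspot SNV.  The PDGFRA exon 18 assay carries the
    spike-in control, mirroring how the controls are deployed in
    practice.
    """
    assays = []
    for assay_id, gene, exon, seq, fl, rl in _DEMO_ASSAYS:
        assays.append(
            Assay(
                assay_id=assay_id,
                gene=gene,
                exon=exon,
                amplicon_seq=seq,
                fwd_primer=seq[:fl],
                rev_primer=seq[-rl:],
                target_window=(fl + 2, len(seq) - rl - 2),
            )
        )
    by_id = {a.assay_id: a for a in assays}

    def snv(assay_id: str, pos: int, name: str) -> TargetVariant:
        ref = by_id[assay_id].amplicon_seq[pos]
        return TargetVariant(assay_id, pos, ref, _OTHER_BASE[ref], "SNV", "resistance", name)

    kit11 = by_id["KIT_11"].amplicon_seq
    dpos, dref, dalt = left_normalize_indel(kit11, 40, kit11[40:46], "")
    variants = [
        TargetVariant("KIT_11", dpos, dref, dalt, "DEL", "tumor_specific", "KIT ex11 del6"),
        snv("KIT_13", 40, "KIT ex13 resistance SNV"),
        snv("KIT_14", 36, "KIT ex14 resistance SNV"),
        snv("KIT_17", 45, "KIT ex17 resistance SNV"),
        snv("PDGFRA_18", 41, "PDGFRA ex18 resistance SNV"),
    ]
    spike_assay = by_id["PDGFRA_18"]
    spikeins = [SpikeInControl("PDGFRA_18", make_spikein_sequence(spike_assay), spikein_count)]
    panel = PatientPanel(patient_id, assays, variants, spikeins)
    violations = validate_panel(panel)
    if violations:  # pragma: no cover - construction bug guard
        raise PanelValidationError(violations)
    return panel
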