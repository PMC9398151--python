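import pytest
from hypothesis import settings

import umicall as uc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel() -> uc.PatientPanel:
    return uc.demo_panel()


@pytest.fixture(scope="session")
def tumor_variant(panel) -> uc.TargetVariant:
    return panel.tumor_variant


def make_reads(panel, molecules, umi_prefix="UMI", reads_per_molecule=5, umi_length=12):
    """Hand-built deterministic reads: one entry per molecule.

    ``molecules`` is a list of (assay_id, sequence) pairs; molecule i
    gets a unique deterministic UMI and ``reads_per_molecule`` identical
    error-free reads.
    """
    out = []
    for i, (assay_id, seq) in enumerate(molecules):
        # unique deterministic UMI: molecule index in base 4
        digits = []
        x = i
        for _ in range(umi_length):
            digits.append("ACGT"[x % 4])
            x //= 4
        umi = "".join(digits)
        for j in range(reads_per_molecule):
            out.append((f"m{i}_r{j}", umi + seq))
    return out
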