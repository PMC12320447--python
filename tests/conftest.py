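import pandas as pd
import pytest

from seedscreen import enrichment as enr
from seedscreen import simulate as sim
from seedscreen.library_design import Segment, load_blosum
from seedscreen.quant import load_members, quantify_fastq


@pytest.fixture(scope="session")
def blosum():
    return load_blosum()


@pytest.fixture(scope="session")
def toy_segment():
    # natives N, D, K: every chosen substitution has >= 2 codons and every
    # native codon has a synonym, so the closed-form count is exercised fully
    return Segment(protein="NDK", reference_dna="AATGATAAA")


@pytest.fixture(scope="session")
def default_screen(tmp_path_factory):
    """The default synthetic sort-seq screen, simulated and quantified once.

    Full desk scale: every member of the default scanning design, 50k cells,
    100k reads per bin, seed 42.
    """
    outdir = tmp_path_factory.mktemp("screen")
    segment, members = sim.default_screen_members(seed=42)
    truth = sim.make_screen_truth(members, seed=42)
    paths = sim.simulate_sort_screen(members, truth, outdir)
    loaded = load_members(paths["members"])
    tables = {
        name: quantify_fastq(paths[name], loaded, sim.DEFAULT_ANCHORS, sample_id=name)
        for name in ("input", "bin_neg", "bin_pos")
    }
    return {
        "segment": segment,
        "members": loaded,
        "truth": truth,
        "paths": paths,
        "tables": tables,
    }


@pytest.fixture(scope="session")
def default_screen_records(default_screen):
    tables = default_screen["tables"]
    pos = enr.fold_enrichment(tables["bin_pos"], tables["input"])
    neg = enr.fold_enrichment(tables["bin_neg"], tables["input"])
    return enr.conservation_ratio(pos, neg)


def make_abundance_table(counts, control_classes=None, sample_id="s"):
    """AbundanceTable from a plain {member_id: count} dict (test helper)."""
    from seedscreen.quant import compute_abundance

    control_classes = control_classes or {}
    members = pd.DataFrame(
        {
            "member_id": list(counts),
            "position": [101 + i for i in range(len(counts))],
            "native_aa": "D",
            "variant_aa": "E",
            "codon": "GAG",
            "control_class": [
                control_classes.get(m, "substitution") for m in counts
            ],
            "oligo_sequence": [f"SEQ{i}" for i in range(len(counts))],
        }
    )
    return compute_abundance(counts, members, sample_id=sample_id)
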