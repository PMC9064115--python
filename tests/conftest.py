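"""Shared fixtures: tiny on-the-fly profile files and small synthetic specs."""

from __future__ import annotations

import numpy as np
import pytest

from presabs.profiles_io import ProfileTable, TaxonLineage
from presabs.synthetic_data import PrevalenceSignal, ReadDepth, SyntheticSpec

METAPHLAN_TEXT = """\
#mpa_v30_CHOCOPhlAn_201901
clade_name\tS1\tS2\tS3
k__Bacteria\t100.0\t100.0\t100.0
k__Bacteria|p__Firmicutes\t80.0\t55.0\t70.0
k__Bacteria|p__Bacteroidetes\t20.0\t45.0\t30.0
k__Bacteria|p__Firmicutes|c__Clostridia\t80.0\t55.0\t70.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales\t80.0\t55.0\t70.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Lachnospiraceae\t80.0\t55.0\t70.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Lachnospiraceae|g__Roseburia\t50.0\t30.0\t45.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Lachnospiraceae|g__Blautia\t30.0\t25.0\t25.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Lachnospiraceae|g__Roseburia|s__Roseburia_faecis\t35.0\t10.0\t40.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Lachnospiraceae|g__Roseburia|s__Roseburia_intestinalis\t15.0\t20.0\t5.0
k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Lachnospiraceae|g__Blautia|s__Blautia_obeum\t30.0\t25.0\t25.0
k__Bacteria|p__Bacteroidetes|c__Bacteroidia\t20.0\t45.0\t30.0
k__Bacteria|p__Bacteroidetes|c__Bacteroidia|o__Bacteroidales\t20.0\t45.0\t30.0
k__Bacteria|p__Bacteroidetes|c__Bacteroidia|o__Bacteroidales|f__Bacteroidaceae\t20.0\t45.0\t30.0
k__Bacteria|p__Bacteroidetes|c__Bacteroidia|o__Bacteroidales|f__Bacteroidaceae|g__Bacteroides\t20.0\t45.0\t30.0
k__Bacteria|p__Bacteroidetes|c__Bacteroidia|o__Bacteroidales|f__Bacteroidaceae|g__Bacteroides|s__Bacteroides_vulgatus\t20.0\t45.0\t30.0
k__Bacteria|p__Bacteroidetes|c__Bacteroidia|o__Bacteroidales|f__Bacteroidaceae|g__Bacteroides|s__Bacteroides_vulgatus|t__SGB1814\t20.0\t45.0\t30.0
"""


@pytest.fixture
def metaphlan_file(tmp_path):
    path = tmp_path / "merged_abundance.tsv"
    path.write_text(METAPHLAN_TEXT)
    return path


def make_species_lineages(n: int) -> list[TaxonLineage]:
    from presabs.synthetic_data import synthetic_taxonomy

    return synthetic_taxonomy(n)


def random_profile(
    n_samples: int, n_taxa: int, seed: int = 0, sparsity: float = 0.5,
    closed: bool = True,
) -> ProfileTable:
    rng = np.random.default_rng(seed)
    values = rng.random((n_samples, n_taxa)) * (rng.random((n_samples, n_taxa)) > sparsity)
    values[values.sum(axis=1) == 0, 0] = 1.0  # no empty samples
    if closed:
        values = values / values.sum(axis=1, keepdims=True)
    else:
        values = values / (values.sum(axis=1, keepdims=True) * 2)
    return ProfileTable(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        taxa=make_species_lineages(n_taxa),
        values=values,
        rank="species",
    )


@pytest.fixture
def small_signal_spec() -> SyntheticSpec:
    """A quick prevalence-shift cohort: strong signal, modest size."""
    return SyntheticSpec(
        n_control=30,
        n_case=30,
        n_taxa=60,
        prevalence_signal=PrevalenceSignal(indices=tuple(range(8)), delta=0.6),
        read_depth=ReadDepth(mean_depth=100_000),
        seed=11,
    )


@pytest.fixture
def null_spec() -> SyntheticSpec:
    """No planted signal: labels are independent of the profiles."""
    return SyntheticSpec(
        n_control=30, n_case=30, n_taxa=60,
        read_depth=ReadDepth(mean_depth=100_000), seed=5,
    )
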