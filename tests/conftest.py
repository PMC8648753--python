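import pytest

from stringagg.fixtures import FixtureSpec, generate_de_tables, generate_enrichment_fixture
from stringagg.string_client import EnrichmentRecord


def make_record(
    term_id: str,
    fdr: float,
    genes: tuple[str, ...] = ("A", "B"),
    kind: str = "KEGG",
    description: str | None = None,
) -> EnrichmentRecord:
    return EnrichmentRecord(
        kind=kind,
        term_id=term_id,
        description=description or f"term {term_id}",
        number_of_genes=len(genes),
        number_of_genes_in_background=10 * max(1, len(genes)),
        fdr=fdr,
        gene_labels=tuple(genes),
    )


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(n_comparisons=3, n_terms_per_kind=4, seed=7)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_spec):
    """DE tables + enrichment folders + ground truth for a 3-comparison run."""
    root = tmp_path_factory.mktemp("small_dataset")
    de_paths = generate_de_tables(small_spec, root / "de")
    _, truth = generate_enrichment_fixture(small_spec, root / "enr")
    return {
        "spec": small_spec,
        "de_paths": de_paths,
        "enrichment_dir": root / "enr",
        "truth": truth,
    }


@pytest.fixture(scope="session")
def large_spec() -> FixtureSpec:
    """Planted structure at the scale of a 12-comparison study."""
    return FixtureSpec(n_comparisons=12, n_terms_per_kind=8, seed=11)


@pytest.fixture(scope="session")
def large_dataset(tmp_path_factory, large_spec):
    root = tmp_path_factory.mktemp("large_dataset")
    de_paths = generate_de_tables(large_spec, root / "de")
    _, truth = generate_enrichment_fixture(large_spec, root / "enr")
    return {
        "spec": large_spec,
        "de_paths": de_paths,
        "enrichment_dir": root / "enr",
        "truth": truth,
    }
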