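import pytest

from sgbkit.binning import build_hierarchy, make_sgbs
from sgbkit.io_formats import read_catalog, read_fasta
from sgbkit.sketching import build_sketch, pairwise_distances
from sgbkit.synthetic import ScenarioConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default 5-species synthetic cohort: files, ground truth, and catalog."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = ScenarioConfig(seed=42)
    truth = generate_cohort(cfg, out)
    entries = read_catalog(out / "catalog.tsv")
    return {"dir": out, "cfg": cfg, "truth": truth, "entries": entries}


@pytest.fixture(scope="session")
def cohort_bins(cohort):
    """Sketches, distances, and the full SGB/GGB/FGB hierarchy of the cohort."""
    entries = cohort["entries"]
    sketches = [
        build_sketch(read_fasta(e.fasta_path), genome_id=e.mag_id) for e in entries
    ]
    dm = pairwise_distances(sketches)
    sources = {e.mag_id: e.host_category for e in entries}
    sgbs = make_sgbs(dm, sources, threshold=0.05)
    catalog = build_hierarchy(sgbs, dm, sources)
    return {"sketches": sketches, "dm": dm, "sources": sources, "catalog": catalog}
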