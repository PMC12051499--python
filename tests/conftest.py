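import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from igstrand.registry import default_registry

    return default_registry()


@pytest.fixture()
def toy_registry_dir(tmp_path):
    """Write a minimal one-template registry directory and return its path."""
    from igstrand.topologies import IGV

    (tmp_path / "templates.tsv").write_text(
        "template_id\tprotein\tig_type\ttemplate_class\tscop\tpdb_id\tchain\tcluster_id\ttopology\tcomment\n"
        "toyV\ttoy\tIgV\tIg\tn/a\t\t\t1\tigv\tsynthetic toy\n"
    )
    lines = ["template_id\tletter\ti_digit\tj_digit\tstart\tend\tanchor\tcomment"]
    for strand, a, b in IGV.strand_ranges():
        lines.append(
            f"toyV\t{strand.letter}\t{strand.i_digit}\t{strand.j_digit}"
            f"\t{a + 1}\t{b + 1}\t{a + 1 + strand.anchor_offset}\t"
        )
    (tmp_path / "annotations.tsv").write_text("\n".join(lines) + "\n")
    (tmp_path / "clusters.tsv").write_text("cluster_id\trepresentative_id\tn_members\n1\ttoyV\t1\n")
    return tmp_path
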