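import textwrap

import pytest


@pytest.fixture
def single_gene_gff(tmp_path):
    """One gene chr1A:100-200 with two exons."""
    text = textwrap.dedent("""\
        ##gff-version 3
        chr1A\tsrc\tgene\t100\t200\t.\t+\t.\tID=gene1
        chr1A\tsrc\texon\t100\t140\t.\t+\t.\tID=gene1.e1;Parent=gene1
        chr1A\tsrc\texon\t160\t200\t.\t+\t.\tID=gene1.e2;Parent=gene1
        """)
    path = tmp_path / "one_gene.gff3"
    path.write_text(text)
    return path


@pytest.fixture
def twelve_gene_gff(tmp_path):
    """Twelve genes, four per subgenome, on chromosomes 1A/1B/1D."""
    lines = ["##gff-version 3"]
    for sub in "ABD":
        for i in range(1, 5):
            start = 1000 * i
            lines.append(
                f"chr1{sub}\tsrc\tgene\t{start}\t{start + 500}\t.\t+\t.\t"
                f"ID=g{sub}{i}")
    path = tmp_path / "twelve.gff3"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def te_tsv(tmp_path):
    """Three TE records: one repeat_region, one nested, one fragment."""
    text = (
        "te_id\tchrom\tstart\tstop\tstatus\tname\n"
        "t1\tchr1A\t150\t300\trepeat_region\tDTT_famn14\n"
        "t2\tchr1A\t160\t250\tnested\tDTT_famn14\n"
        "t3\tchr1A\t400\t500\tfragment\tRLC_famc1.6\n"
    )
    path = tmp_path / "tes.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def partition_5regions():
    """Chromosome of 1000 bp split into the five canonical regions."""
    from tebias.annotations_io import RegionPartition
    return RegionPartition({
        "chr1A": [("R1", 1, 200), ("R2a", 201, 400), ("C", 401, 600),
                  ("R2b", 601, 800), ("R3", 801, 1000)],
    })


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded synthetic dataset shared by slower integration tests."""
    from tebias.simulate import (PlantedEffect, PlantedGO, SimulationConfig,
                                 generate_dataset)
    config = SimulationConfig(
        seed=42, n_dyads=80, n_triads=600, n_tetrads=20,
        planted_effects=[
            PlantedEffect("DTM", "suppressed_vs_notsuppressed", 4.0)],
        planted_go=[PlantedGO("GO:0000003", "DTT", 8.0)],
    )
    return generate_dataset(config)
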