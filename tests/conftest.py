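import numpy as np
import pytest

from neotcr import synthdata, vdj


@pytest.fixture(scope="session")
def small_config():
    return synthdata.SimConfig(
        n_clonotypes=100,
        n_cells_pre=400,
        n_cells_post=400,
        n_genes=120,
        spikes=[(40, 30.0)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    return synthdata.generate_repertoire_pair(small_config)


@pytest.fixture(scope="session")
def small_adata(small_config, small_pair):
    _, _, truth = small_pair
    return synthdata.generate_gex(small_config, truth)


@pytest.fixture()
def contig_csv(tmp_path):
    """Write a contig DataFrame to CSV and return the path."""

    def _write(df, name="contigs.csv"):
        path = tmp_path / name
        synthdata.write_contigs(df, path)
        return path

    return _write


def cells_from_frame(df, tmp_path, name="contigs.csv"):
    path = tmp_path / name
    synthdata.write_contigs(df, path)
    return vdj.assemble_cells(vdj.read_contigs(path))


def make_contig_row(
    barcode,
    chain="TRB",
    cdr3="CASSLGQAYEQYF",
    v="TRBV6-5",
    j="TRBJ2-7",
    productive="True",
    **overrides,
):
    row = {
        "barcode": barcode,
        "is_cell": "True",
        "contig_id": f"{barcode}_contig",
        "high_confidence": "True",
        "length": 540,
        "chain": chain,
        "v_gene": v,
        "d_gene": "None",
        "j_gene": j,
        "c_gene": "TRBC1" if chain == "TRB" else "TRAC",
        "full_length": "True",
        "productive": productive,
        "cdr3": cdr3,
        "cdr3_nt": "TGT" * (len(cdr3) if cdr3 else 1),
        "reads": 500,
        "umis": 20,
        "raw_clonotype_id": "clonotype1",
    }
    row.update(overrides)
    return row


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
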