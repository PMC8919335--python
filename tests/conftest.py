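import pandas as pd
import pytest

from ribodra import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with planted DE and DRA effects."""
    cfg = SimConfig(
        n_genes=2000,
        frac_de=0.10,
        frac_dra=0.10,
        frac_signature=0.02,
        de_log2fc_mean=1.5,
        de_log2fc_sd=0.1,
        dra_log2ratio_mean=1.5,
        dra_log2ratio_sd=0.1,
        noise_cv=0.1,
        zero_input_prob=0.01,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def tiny_design():
    """Two WT and two MUT animals, one input + one IP sample each."""
    rows = []
    for animal, geno in [("wt1", "WT"), ("wt2", "WT"),
                         ("mut1", "MUT"), ("mut2", "MUT")]:
        for frac in ("input", "IP"):
            rows.append({"sample_id": f"{animal}_{frac}", "animal_id": animal,
                         "genotype": geno, "fraction": frac})
    return pd.DataFrame(rows)


def matrices_from(design, gene_values):
    """Build paired input/IP matrices from {gene: {sample: value}} dicts."""
    inp_cols = [s for s in design["sample_id"] if s.endswith("_input")]
    ip_cols = [s for s in design["sample_id"] if s.endswith("_IP")]
    genes = list(gene_values)
    inp = pd.DataFrame(
        {c: [gene_values[g][c] for g in genes] for c in inp_cols},
        index=pd.Index(genes, name="gene_id"),
    )
    ip = pd.DataFrame(
        {c: [gene_values[g][c] for g in genes] for c in ip_cols},
        index=pd.Index(genes, name="gene_id"),
    )
    return inp, ip
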