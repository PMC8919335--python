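"""Synthetic paired Input/IP datasets with planted ground truth.

Emulates a RiboTag-style experiment: each animal contributes one total-RNA
(input) sample and one ribosome-IP sample, and differential effects are
planted on transcript abundance (input), on ribosome association
(IP/input ratio), or jointly on both.  Every stochastic choice flows
through one seeded generator so a config reproduces its dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "FociSimConfig",
    "SimulationError",
    "simulate_dataset",
    "simulate_reference_profiles",
    "simulate_foci_images",
]

AUTOSOMES = [str(i) for i in range(1, 20)]


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the paired Input/IP expression simulator.

    Defaults mirror the study design being emulated: 3 wild-type and 4
    mutant animals, differentially expressed genes biased towards reduced
    abundance in the mutant (61%), and differentially ribosome-associated
    genes biased towards increased association in the mutant (69%).

    Effect sizes are drawn on the log2 scale: a gene planted as DE gets a
    log2 fold change on its input abundance, a DRA gene a log2 shift of
    its IP/input ratio, and a "signature" gene a moderate abundance
    decrease joint with a ribosome-association increase.
    """

    n_genes: int = 10_000
    n_wt_animals: int = 3
    n_mut_animals: int = 4
    frac_de: float = 0.0
    frac_de_down_in_mut: float = 0.61
    frac_dra: float = 0.0
    frac_dra_up_in_mut: float = 0.69
    frac_signature: float = 0.0
    de_log2fc_mean: float = 1.0
    de_log2fc_sd: float = 0.25
    dra_log2ratio_mean: float = 1.0
    dra_log2ratio_sd: float = 0.25
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    ra_baseline_log2_sd: float = 0.25
    noise_cv: float = 0.2
    zero_input_prob: float = 0.0
    frac_chrX: float = 0.04
    frac_chrY: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        props = {
            "frac_de": self.frac_de,
            "frac_de_down_in_mut": self.frac_de_down_in_mut,
            "frac_dra": self.frac_dra,
            "frac_dra_up_in_mut": self.frac_dra_up_in_mut,
            "frac_signature": self.frac_signature,
            "zero_input_prob": self.zero_input_prob,
            "frac_chrX": self.frac_chrX,
            "frac_chrY": self.frac_chrY,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise SimulationError(f"{name}={value} must lie in [0, 1]")
        if self.frac_de + self.frac_dra + self.frac_signature > 1.0:
            raise SimulationError(
                "frac_de + frac_dra + frac_signature must not exceed 1"
            )
        if self.frac_chrX + self.frac_chrY >= 1.0:
            raise SimulationError("frac_chrX + frac_chrY must be < 1")
        if self.n_genes < 1:
            raise SimulationError("n_genes must be positive")
        if self.n_wt_animals < 2 or self.n_mut_animals < 2:
            raise SimulationError(
                "at least 2 animals per genotype are required for the Welch test"
            )
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")
        if self.baseline_log_sd < 0 or self.ra_baseline_log2_sd < 0:
            raise SimulationError("dispersion parameters must be >= 0")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=shape)


def _plant_effects(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    """Assign each gene a category and draw its true effect sizes."""
    n = cfg.n_genes
    cats = rng.choice(
        ["none", "de", "dra", "signature"],
        size=n,
        p=[
            1.0 - cfg.frac_de - cfg.frac_dra - cfg.frac_signature,
            cfg.frac_de,
            cfg.frac_dra,
            cfg.frac_signature,
        ],
    )
    true_log2fc = np.zeros(n)
    true_shift = np.zeros(n)
    de_dir = np.array(["none"] * n, dtype=object)
    dra_dir = np.array(["none"] * n, dtype=object)

    de_mask = cats == "de"
    n_de = int(de_mask.sum())
    if n_de:
        mags = np.abs(rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd, n_de))
        down = rng.random(n_de) < cfg.frac_de_down_in_mut
        true_log2fc[de_mask] = np.where(down, -mags, mags)
        de_dir[de_mask] = np.where(down, "down_in_mut", "up_in_mut")

    dra_mask = cats == "dra"
    n_dra = int(dra_mask.sum())
    if n_dra:
        mags = np.abs(rng.normal(cfg.dra_log2ratio_mean, cfg.dra_log2ratio_sd, n_dra))
        up = rng.random(n_dra) < cfg.frac_dra_up_in_mut
        true_shift[dra_mask] = np.where(up, mags, -mags)
        dra_dir[dra_mask] = np.where(up, "up_in_mut", "down_in_mut")

    # Signature genes combine a moderate abundance decrease with a
    # ribosome-association increase (the elongation-defect-like pattern).
    sig_mask = cats == "signature"
    n_sig = int(sig_mask.sum())
    if n_sig:
        fc = np.abs(rng.normal(cfg.de_log2fc_mean, cfg.de_log2fc_sd, n_sig)) / 2.0
        sh = np.abs(rng.normal(cfg.dra_log2ratio_mean, cfg.dra_log2ratio_sd, n_sig))
        true_log2fc[sig_mask] = -fc
        true_shift[sig_mask] = sh
        de_dir[sig_mask] = "down_in_mut"
        dra_dir[sig_mask] = "up_in_mut"

    is_de = de_mask | sig_mask
    is_dra = dra_mask | sig_mask
    return pd.DataFrame(
        {
            "is_de": is_de,
            "de_direction": de_dir,
            "true_log2fc": true_log2fc,
            "is_dra": is_dra,
            "dra_direction": dra_dir,
            "true_log2_ra_shift": true_shift,
            "signature_class": np.where(sig_mask, "elongation_defect", "none"),
        }
    )


def _assign_chromosomes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    p_auto = (1.0 - cfg.frac_chrX - cfg.frac_chrY) / len(AUTOSOMES)
    labels = AUTOSOMES + ["X", "Y"]
    probs = [p_auto] * len(AUTOSOMES) + [cfg.frac_chrX, cfg.frac_chrY]
    return rng.choice(labels, size=cfg.n_genes, p=probs)


def simulate_dataset(config: SimConfig):
    """Simulate paired Input/IP TPM matrices with planted DE/DRA effects.

    Returns
    -------
    input_matrix, ip_matrix : pandas.DataFrame
        Genes x samples TPM tables sharing the gene index.
    design : pandas.DataFrame
        Columns sample_id, animal_id, genotype, fraction; one input and
        one IP sample per animal.
    annotation : pandas.DataFrame
        gene_id -> chromosome map (mouse-like labels 1..19, X, Y).
    truth : pandas.DataFrame
        Per-gene planted ground truth (flags, directions, effect sizes,
        chromosome) for parameter-recovery testing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    truth = _plant_effects(rng, config)
    truth.index = pd.Index(gene_ids, name="gene_id")
    chrom = _assign_chromosomes(rng, config)
    truth["chromosome"] = chrom
    annotation = pd.DataFrame({"chromosome": chrom},
                              index=pd.Index(gene_ids, name="gene_id"))

    animals = [f"wt{i + 1}" for i in range(config.n_wt_animals)] + [
        f"mut{i + 1}" for i in range(config.n_mut_animals)
    ]
    genotypes = ["WT"] * config.n_wt_animals + ["MUT"] * config.n_mut_animals
    design = pd.DataFrame(
        [
            {
                "sample_id": f"{a}_{frac}",
                "animal_id": a,
                "genotype": g,
                "fraction": frac,
            }
            for a, g in zip(animals, genotypes)
            for frac in ("input", "IP")
        ]
    )

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             config.n_genes)
    # Gene-specific baseline ribosome association, identical across genotypes.
    base_ra = 2.0 ** rng.normal(0.0, config.ra_baseline_log2_sd, config.n_genes)

    fc = truth["true_log2fc"].to_numpy()
    shift = truth["true_log2_ra_shift"].to_numpy()

    input_cols, ip_cols = {}, {}
    for animal, geno in zip(animals, genotypes):
        mut = geno == "MUT"
        mean_abund = baseline * (2.0**fc if mut else 1.0)
        inp = mean_abund * _lognormal_noise(rng, config.noise_cv, config.n_genes)
        ra = base_ra * (2.0**shift if mut else 1.0)
        ip = inp * ra * _lognormal_noise(rng, config.noise_cv, config.n_genes)
        if config.zero_input_prob > 0:
            inp = np.where(rng.random(config.n_genes) < config.zero_input_prob,
                           0.0, inp)
        input_cols[f"{animal}_input"] = inp
        ip_cols[f"{animal}_IP"] = ip

    idx = pd.Index(gene_ids, name="gene_id")
    input_matrix = pd.DataFrame(input_cols, index=idx)
    ip_matrix = pd.DataFrame(ip_cols, index=idx)
    return input_matrix, ip_matrix, design, annotation, truth


def simulate_reference_profiles(n_genes: int, cell_types, seed: int = 0):
    """Simulate a cell-type expression reference with known dominant types.

    Each gene is assigned a dominant cell type in which its expression is
    drawn high; expression in the other types is drawn low.  Returns the
    reference (genes x cell types, nonnegative) and a Series of planted
    dominant types for testing.
    """
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise SimulationError("at least 2 cell types are required")
    if n_genes < 1:
        raise SimulationError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    dominant = rng.choice(cell_types, size=n_genes)
    expr = rng.lognormal(1.0, 0.5, (n_genes, len(cell_types)))
    # dominant cell type strictly exceeds the gene's other values
    boost = rng.lognormal(1.5, 0.3, n_genes)
    dom_col = np.array([cell_types.index(ct) for ct in dominant])
    rows = np.arange(n_genes)
    expr[rows, dom_col] = expr.max(axis=1) + boost
    reference = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                             columns=cell_types)
    dominant = pd.Series(dominant, index=reference.index, name="dominant")
    return reference, dominant


@dataclass
class FociSimConfig:
    """Parameters of the nuclear-foci image simulator.

    Cells are laid out as disjoint rectangular regions of a label mask;
    foci are square blobs of ``focus_size_px`` pixels painted at
    ``focus_intensity`` over ``background_level``, well separated so that
    connected-component counting at the downstream defaults recovers the
    planted counts exactly when ``noise_sd`` is zero.
    """

    n_images: int = 10
    image_shape: tuple = (128, 128)
    n_cells_per_image: int = 4
    foci_counts: tuple = (0, 1, 2, 3, 4, 5)
    foci_probs: tuple | None = None
    focus_intensity: int = 200
    focus_size_px: int = 12
    background_level: int = 20
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_images < 1 or self.n_cells_per_image < 1:
            raise SimulationError("n_images and n_cells_per_image must be positive")
        if not (0 <= self.background_level < self.focus_intensity <= 255):
            raise SimulationError(
                "need 0 <= background_level < focus_intensity <= 255"
            )
        if self.focus_size_px < 1:
            raise SimulationError("focus_size_px must be >= 1")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.foci_probs is not None and len(self.foci_probs) != len(self.foci_counts):
            raise SimulationError("foci_probs must match foci_counts in length")


def simulate_foci_images(config: FociSimConfig):
    """Simulate grayscale images, per-cell label masks and true foci counts.

    Returns (images, masks, true_counts): lists of uint8 images and uint16
    masks, and a DataFrame with columns image, cell_id, true_count.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    ncells = config.n_cells_per_image

    # Grid layout of cells: disjoint rectangles with a 2-px gutter.
    grid = int(np.ceil(np.sqrt(ncells)))
    cell_h, cell_w = h // grid, w // grid
    side = int(np.ceil(np.sqrt(config.focus_size_px)))
    # Foci sit on an internal sub-grid with >=2-px separation so blobs
    # never merge under 8-connectivity.
    pitch = side + 2
    slots_r = max((cell_h - 4) // pitch, 0)
    slots_c = max((cell_w - 4) // pitch, 0)
    max_foci = max(config.foci_counts)
    if slots_r * slots_c < max_foci:
        raise SimulationError(
            f"cells of {cell_h}x{cell_w} px cannot hold {max_foci} "
            f"non-overlapping foci of {config.focus_size_px} px"
        )

    probs = config.foci_probs
    images, masks, rows = [], [], []
    for img_i in range(config.n_images):
        img = np.full((h, w), config.background_level, dtype=float)
        mask = np.zeros((h, w), dtype=np.uint16)
        for cell in range(ncells):
            gr, gc = divmod(cell, grid)
            r0, c0 = gr * cell_h, gc * cell_w
            mask[r0 + 1:r0 + cell_h - 1, c0 + 1:c0 + cell_w - 1] = cell + 1
            count = int(rng.choice(config.foci_counts, p=probs))
            slots = rng.choice(slots_r * slots_c, size=count, replace=False)
            for s in slots:
                sr, sc = divmod(int(s), slots_c)
                fr = r0 + 2 + sr * pitch
                fc = c0 + 2 + sc * pitch
                blob = np.zeros((side, side), dtype=bool)
                blob.ravel()[: config.focus_size_px] = True
                img[fr:fr + side, fc:fc + side][blob] = config.focus_intensity
            rows.append({"image": img_i, "cell_id": cell + 1, "true_count": count})
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        images.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
        masks.append(mask)
    true_counts = pd.DataFrame(rows)
    return images, masks, true_counts
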