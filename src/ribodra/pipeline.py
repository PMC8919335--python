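"""End-to-end orchestration: simulate or load, screen, enrich, profile.

`run_pipeline` chains the stages — RA/DRA screen on paired Input/IP
matrices, the DE decision rule on the input fraction, X-chromosome
enrichment statistics, and optional cell-type percent-expression
profiles — writing every stage's table plus a run manifest (config hash,
input hashes, per-stage gene counts) so a run is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, io
from .celltype import percent_expression, summarize_list_profile
from .de import call_de, de_direction_and_magnitude_summary
from .enrichment import direction_bias_x_vs_autosome, x_overrepresentation
from .ra import call_dra, compute_ra, direction_summary
from .simulate import SimConfig, simulate_dataset, simulate_reference_profiles

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and thresholds of a full pipeline run.

    Either `sim` is given (a SimConfig: the dataset is simulated) or the
    three paths input_path/ip_path/design_path point at delimited files.
    """

    outdir: str = "ribodra_run"
    sim: SimConfig | None = None
    input_path: str | None = None
    ip_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    reference_path: str | None = None
    alpha: float = 0.05
    score_threshold: float = 0.95
    log2_ratios: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if not 0.0 < self.score_threshold <= 1.0:
            raise ValueError(
                f"score_threshold={self.score_threshold} outside (0, 1]"
            )
        if self.sim is None:
            for name in ("input_path", "ip_path", "design_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "alpha": config.alpha,
        "score_threshold": config.score_threshold,
        "seed": config.seed,
        "input_hashes": {},
        "counts": {},
    }

    if config.sim is not None:
        sim_cfg = config.sim
        inp, ip, design, annotation, truth = simulate_dataset(sim_cfg)
        io.write_expression_matrix(inp, outdir / "input_tpm.tsv")
        io.write_expression_matrix(ip, outdir / "ip_tpm.tsv")
        io.write_design(design, outdir / "design.tsv")
        io.write_annotation(annotation, outdir / "annotation.tsv")
        truth.to_csv(outdir / "sim_truth.tsv", sep="\t")
        manifest["sim_config"] = asdict(sim_cfg)
    else:
        inp = io.read_expression_matrix(config.input_path)
        ip = io.read_expression_matrix(config.ip_path)
        design = io.read_design(config.design_path)
        if set(inp.index) != set(ip.index):
            raise ValueError(
                "input and IP matrices cover different gene sets"
            )
        annotation = (io.read_annotation(config.annotation_path)
                      if config.annotation_path else None)
        for name in ("input_path", "ip_path", "design_path"):
            manifest["input_hashes"][name] = _sha256(getattr(config, name))

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(
            {k: v for k, v in manifest.items() if k not in ("timestamp",)},
            sort_keys=True, default=str,
        ).encode()
    ).hexdigest()
    manifest["counts"]["genes_input"] = int(len(inp))

    # Stage 1: ribosome association + DRA screen
    ra_table = compute_ra(inp, ip, design)
    ra_out = ra_table.ra.copy()
    ra_out.to_csv(outdir / "ra_table.tsv", sep="\t")
    dra = call_dra(ra_table, alpha=config.alpha, log2=config.log2_ratios)
    dra.to_csv(outdir / "dra_results.tsv", sep="\t")
    n_dra, pct_up_mut, pct_up_wt = direction_summary(dra)
    manifest["counts"]["genes_zero_input_filtered"] = ra_table.n_filtered_genes
    manifest["counts"]["genes_ra_tested"] = int(len(ra_table.ra))
    manifest["counts"]["n_dra"] = n_dra
    manifest["dra_pct_up_in_mut"] = pct_up_mut

    # Stage 2: DE decision rule on the input fraction
    de = call_de(inp, design, score_threshold=config.score_threshold)
    de.to_csv(outdir / "de_results.tsv", sep="\t")
    n_de, pct_down, pct_fc2 = de_direction_and_magnitude_summary(de)
    manifest["counts"]["n_de"] = n_de
    manifest["de_pct_down_in_mut"] = pct_down
    manifest["de_pct_fc_ge_2"] = pct_fc2

    # Stage 3: X-chromosome enrichment (needs annotation and DE calls)
    if annotation is not None and n_de > 0:
        enrich: dict = {}
        try:
            fold, p = x_overrepresentation(de, annotation)
            enrich["x_overrepresentation"] = {"fold_enrichment": fold,
                                              "p_value": p}
        except ValueError as exc:
            enrich["x_overrepresentation"] = {"error": str(exc)}
        try:
            bias = direction_bias_x_vs_autosome(de, annotation)
            enrich["direction_bias_x_vs_autosome"] = {
                "table": bias.table.tolist(),
                "odds_ratio": bias.odds_ratio,
                "p_value": bias.p_value,
            }
        except ValueError as exc:
            enrich["direction_bias_x_vs_autosome"] = {"error": str(exc)}
        with open(outdir / "enrichment.json", "w") as fh:
            json.dump(enrich, fh, indent=2, default=float)
        manifest["enrichment"] = enrich

    # Stage 4: cell-type percent-expression profile of called gene sets
    if config.reference_path is not None:
        reference = pd.read_csv(config.reference_path, sep="\t", index_col=0)
    elif config.sim is not None:
        reference, _ = simulate_reference_profiles(
            len(inp), ["somatic", "mitotic", "meiotic", "post_meiotic"],
            seed=config.seed,
        )
        reference.index = inp.index
    else:
        reference = None
    if reference is not None:
        for label, table in (("de", de[de["is_de"]]),
                             ("dra", dra[dra["is_dra"]])):
            if len(table) == 0:
                continue
            prof = percent_expression(table.index, reference)
            prof.to_csv(outdir / f"celltype_profile_{label}.tsv", sep="\t")
            summary = summarize_list_profile(prof)
            manifest[f"celltype_mean_pct_{label}"] = summary.to_dict()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
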