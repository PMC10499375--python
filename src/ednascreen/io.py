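"""Readers, writers, schema validation and pipeline configuration.

All tabular artifacts are UTF-8 CSV with ISO-8601 dates. The pipeline
configuration is a YAML file with sections mirroring the stages; unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .quantify import fit_curves, qc_controls, reads_to_copies
from .screen import UICScreen
from .synthdata import (SpikeInDesign, generate_read_table, make_network,
                        simulate_experiment)

__all__ = ["SCHEMAS", "read_table", "read_reads", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

#: required columns and unique-key columns per logical table
SCHEMAS: dict[str, dict] = {
    "copies": {"columns": ["sample_id", "plot", "date", "taxon", "copies_per_ml"],
               "key": ["sample_id", "taxon"], "dates": ["date"]},
    "manifest": {"columns": ["sample_id", "plot", "date", "filter_type",
                             "sample_class", "water_ml", "elution_ul"],
                 "key": ["sample_id"], "dates": ["date"]},
    "standards": {"columns": ["standard_id", "copies_per_ul"],
                  "key": ["standard_id"], "dates": []},
    "growth": {"columns": ["plot", "date", "growth_rate"],
               "key": ["plot", "date"], "dates": ["date"]},
    "climate": {"columns": ["plot", "date", "temperature"],
                "key": ["plot", "date"], "dates": ["date"]},
    "screen": {"columns": ["taxon", "tested", "best_tp", "te", "p_value", "causal"],
               "key": ["taxon"], "dates": []},
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises a descriptive error on a missing column or duplicated key.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema: {schema!r}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path)
    for col in spec["columns"]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column: {col}")
    for col in spec["dates"]:
        df[col] = pd.to_datetime(df[col], format="ISO8601").dt.date
    dup = df.duplicated(subset=spec["key"])
    if dup.any():
        first = df.loc[dup, spec["key"]].iloc[0].tolist()
        raise ValueError(f"{path}: duplicate key {tuple(first)} on {spec['key']}")
    return df


def read_reads(path) -> pd.DataFrame:
    """Read a wide read table (rows = samples, columns = taxa + standards)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing column: sample_id")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate key ({dup!r},) on ['sample_id']")
    return df.set_index("sample_id")


def wide_series(table: pd.DataFrame, value: str) -> tuple[list, np.ndarray]:
    """Pivot a long (plot, date, value) table to (plots, n_days) array."""
    wide = table.pivot_table(index="plot", columns="date", values=value,
                             aggfunc="mean").sort_index()
    wide = wide[sorted(wide.columns)]
    return wide.index.tolist(), wide.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# configuration


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in [{context}]: {sorted(unknown)}")
    return cls(**data)


@dataclass
class CommunityConfig:
    n_taxa: int = 20
    n_causes: int = 3
    n_days: int = 100
    n_plots: int = 3
    noise_sd: float = 0.01
    growth_noise_sd: float = 0.1
    copies_scale: float = 1e5
    driver_effect: float = 0.8
    climate_effect: float = 0.08
    coupling_strength: float = 0.05


@dataclass
class ObservationConfig:
    depth_factor: float = 10.0
    noise_model: str = "poisson"
    depth_sd_log: float = 0.3
    water_ml: float = 200.0
    elution_ul: float = 100.0
    qc_threshold: float = 10.0


@dataclass
class ScreenConfig:
    tp_min: int = -14
    tp_max: int = 0
    alpha: float = 0.05
    B: int = 1000
    E_max: int = 10
    tau: int = 1
    k: int | None = None
    theiler: int = 0
    min_detection_frac: float = 0.1


@dataclass
class PipelineConfig:
    """Complete, reproducible description of one pipeline run."""

    seed: int = 0
    outdir: str = "ednascreen_out"
    community: CommunityConfig = field(default_factory=CommunityConfig)
    observation: ObservationConfig = field(default_factory=ObservationConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sections = {"community": CommunityConfig, "observation": ObservationConfig,
                    "screen": ScreenConfig}
        unknown = set(raw) - set(sections) - {"seed", "outdir"}
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {}
        for name, scls in sections.items():
            kwargs[name] = _from_mapping(scls, raw.get(name, {}) or {}, name)
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "outdir" in raw:
            kwargs["outdir"] = str(raw["outdir"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# pipeline


def _write_simulation(cfg: PipelineConfig, outdir: Path) -> None:
    cc = cfg.community
    ss = np.random.SeedSequence(cfg.seed)
    s_net, s_sim, s_obs = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    network = make_network(n_taxa=cc.n_taxa, n_causes=cc.n_causes,
                           driver_effect=cc.driver_effect,
                           climate_effect=cc.climate_effect,
                           coupling_strength=cc.coupling_strength, seed=s_net)
    traj, _ = simulate_experiment(network, n_days=cc.n_days, n_plots=cc.n_plots,
                                  seed=s_sim, noise_sd=cc.noise_sd,
                                  growth_noise_sd=cc.growth_noise_sd,
                                  copies_scale=cc.copies_scale)
    oc = cfg.observation
    design = SpikeInDesign()
    reads, manifest = generate_read_table(
        traj, design, depth_factor=oc.depth_factor, noise_model=oc.noise_model,
        seed=s_obs, depth_sd_log=oc.depth_sd_log, water_ml=oc.water_ml,
        elution_ul=oc.elution_ul)

    reads.to_csv(outdir / "reads.csv")
    manifest.to_csv(outdir / "manifest.csv", index=False)
    design.as_frame().to_csv(outdir / "standards.csv", index=False)

    taxa = [f"Taxa{i+1:03d}" for i in range(traj.n_taxa)]
    truth = [{"plot": plot, "date": date.date().isoformat(), "taxon": taxon,
              "copies_per_ml": traj.abundances[p, d, i]}
             for p, plot in enumerate(traj.plots)
             for d, date in enumerate(traj.dates)
             for i, taxon in enumerate(taxa)]
    pd.DataFrame(truth).to_csv(outdir / "truth.csv", index=False)

    rows = [{"plot": plot, "date": date.date().isoformat(),
             "growth_rate": traj.growth_rate[p, d],
             "temperature": traj.temperature[p, d]}
            for p, plot in enumerate(traj.plots)
            for d, date in enumerate(traj.dates)]
    long = pd.DataFrame(rows)
    long[["plot", "date", "growth_rate"]].to_csv(outdir / "growth.csv", index=False)
    long[["plot", "date", "temperature"]].to_csv(outdir / "climate.csv", index=False)

    net_doc = {"n_taxa": network.n_taxa,
               "true_causes": [taxa[i] for i in network.true_causes],
               "growth_drivers": [[taxa[i], lag, coef]
                                  for i, lag, coef in network.growth_drivers],
               "climate_driver": list(network.climate_driver),
               "interaction_matrix": network.interaction_matrix.tolist(),
               "intrinsic_rates": network.intrinsic_rates.tolist()}
    (outdir / "network.json").write_text(json.dumps(net_doc, indent=1))


def quantify_stage(reads: pd.DataFrame, standards: pd.DataFrame,
                   manifest: pd.DataFrame, qc_threshold: float = 10.0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit per-sample curves and convert a read table to a CopyTable."""
    curves = fit_curves(reads, standards)
    copies = reads_to_copies(reads, curves, manifest, standards)
    qc = qc_controls(reads, manifest, standards, qc_threshold)
    return copies, qc


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run simulate -> quantify -> screen, writing all artifacts as CSV.

    Every stage reads the previous stage's files back from disk, so the
    artifacts on disk are the complete interface between stages. Returns
    the artifact paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("ednascreen %s pipeline run: seed=%d outdir=%s",
                __version__, config.seed, outdir)
    logger.info("config: %s", dataclasses.asdict(config))

    _write_simulation(config, outdir)

    reads = read_reads(outdir / "reads.csv")
    standards = read_table(outdir / "standards.csv", "standards")
    manifest = read_table(outdir / "manifest.csv", "manifest")
    copies, qc = quantify_stage(reads, standards, manifest,
                                config.observation.qc_threshold)
    copies.to_csv(outdir / "copies.csv", index=False)
    qc.to_csv(outdir / "qc.csv", index=False)

    copies = read_table(outdir / "copies.csv", "copies")
    growth_tab = read_table(outdir / "growth.csv", "growth")
    climate_tab = read_table(outdir / "climate.csv", "climate")
    _, growth = wide_series(growth_tab, "growth_rate")
    _, temperature = wide_series(climate_tab, "temperature")

    sc = config.screen
    screen_seed = int(np.random.SeedSequence(config.seed).spawn(4)[3]
                      .generate_state(1)[0] % (2**31))
    est = UICScreen(tp_min=sc.tp_min, tp_max=sc.tp_max, alpha=sc.alpha,
                    E_max=sc.E_max, tau=sc.tau, k=sc.k, B=sc.B,
                    theiler=sc.theiler, min_detection_frac=sc.min_detection_frac,
                    random_state=screen_seed)
    est.fit(copies, growth, climate={"temperature": temperature})
    est.results_.to_csv(outdir / "screen.csv", index=False)
    logger.info("screen: %d/%d taxa flagged causal; conditions=%s",
                int(est.results_["causal"].fillna(False).astype(bool).sum()),
                len(est.results_), est.conditions_)
    return {name: outdir / f"{name}.csv"
            for name in ("reads", "manifest", "standards", "truth", "growth",
                         "climate", "copies", "qc", "screen")}
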