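"""End-to-end orchestration: simulate → extract → search → model.

A run is a pure function of a :class:`RunConfig` (all stages are seeded), so
two runs with the same config produce byte-identical CSV artifacts.  Stages
can also be driven individually from their on-disk artifacts, which is what
the command-line interface does.

Artifacts written under the output directory:

- ``scenes/``            per-plot image/mask TIFFs + ``truth.csv``
- ``vis.csv``            10 vegetation indices per plot
- ``tfs.csv``            48 texture features per plot (+ ``glcm_config.json``)
- ``vi_screen.csv`` / ``tf_screen.csv``   Pearson r, p, selected flags
- ``best_combinations.csv``               best tuple per index family
- ``tensors.npz`` + ``heatmap_<family>.png``  |r| search surfaces
- ``grid.csv``           45-cell combination × model metrics
- ``scatter.csv``        measured vs predicted LAI for the best cell
- ``lai_map.tif``        per-pixel inversion map of one validation plot
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glcm import GLCMConfig, TEXTURE_LABELS, plot_texture_features
from .imagery import read_image, read_mask, vegetation_mask, plot_mean_reflectance
from .indices import VI_NAMES, compute_vis
from .models import (
    MODEL_NAMES,
    default_model_specs,
    enumerate_combinations,
    fit_model,
    grid_table,
    predict_map,
    run_grid,
    split_dataset,
)
from .search import (
    FAMILIES,
    FAMILY_NAMES,
    best_combination_table,
    materialize_index,
    screen_table,
    screen_variables,
    search_family,
)
from .synth import (
    CanopyRadiativeModel,
    ExperimentDesign,
    PlotSample,
    TreatmentEffectModel,
    generate_experiment,
)

__all__ = [
    "RunConfig",
    "extract_features",
    "resolve_feature_blocks",
    "run_simulate",
    "run_extract",
    "run_search",
    "run_model",
    "run_all",
]

logger = logging.getLogger("texlai")

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """Everything a full run depends on; serializable to/from YAML or JSON."""

    outdir: str = "texlai_run"
    generator_seed: int = 42
    split_seed: int = 7
    model_random_state: int = 0
    alpha: float = 0.05
    mask_method: str = "provided-mask"  # or "ndvi-threshold"
    ndvi_threshold: float = 0.3
    families: tuple[str, ...] = FAMILY_NAMES
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    effects: TreatmentEffectModel = field(default_factory=TreatmentEffectModel)
    radiative: CanopyRadiativeModel = field(default_factory=CanopyRadiativeModel)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                    if not callable(getattr(obj, f.name))
                }
            if isinstance(obj, (tuple, list)):
                return [enc(x) for x in obj]
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs: dict = {}
        for name, sub in (
            ("design", ExperimentDesign),
            ("effects", TreatmentEffectModel),
            ("radiative", CanopyRadiativeModel),
            ("glcm", GLCMConfig),
        ):
            if name in d:
                sd = dict(d.pop(name))
                for k, v in list(sd.items()):
                    if isinstance(v, list):
                        sd[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
                kwargs[name] = sub(**sd)
        for k, v in d.items():
            kwargs[k] = tuple(v) if isinstance(v, list) and k == "families" else v
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _log_stage(config: RunConfig, stage: str, **counts) -> None:
    logger.info("stage=%s config=%s %s", stage, config.config_hash(),
                " ".join(f"{k}={v}" for k, v in counts.items()))


def extract_features(
    samples: list[PlotSample], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vegetation-index and texture-feature tables, one aligned row per plot."""
    vi_rows, tf_rows, ids = [], [], []
    for s in samples:
        if config.mask_method == "provided-mask":
            mask = vegetation_mask(s.image, "provided-mask", provided=s.vegetation_mask)
        else:
            mask = vegetation_mask(s.image, "ndvi-threshold", config.ndvi_threshold)
        rec = plot_mean_reflectance(s.image, mask, s.plot_id)
        vi_rows.append(compute_vis(rec).values)
        tf_rows.append(plot_texture_features(s.image, mask, config.glcm, s.plot_id).values)
        ids.append(s.plot_id)
    vis = pd.DataFrame(vi_rows, index=ids)[list(VI_NAMES)]
    tfs = pd.DataFrame(tf_rows, index=ids)[list(TEXTURE_LABELS)]
    vis.index.name = tfs.index.name = "plot_id"
    return vis, tfs


def resolve_feature_blocks(
    vis: pd.DataFrame,
    tfs: pd.DataFrame,
    lai: np.ndarray,
    config: RunConfig,
    best: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """Screen VIs/TFs and materialize best-tuple index columns.

    Returns the combined feature table, the block → column map, and the
    best-combination table used for the TI/TTI columns.  NaN entries in an
    index column (samples outside its finite support) are filled with the
    column median so model fits see complete data.
    """
    if best is None:
        best = best_combination_table(tfs, lai, config.families)
    vi_sel = [s.name for s in screen_variables(vis, lai, config.alpha) if s.selected]
    tf_sel = [s.name for s in screen_variables(tfs, lai, config.alpha) if s.selected]
    features = pd.concat([vis, tfs], axis=1)
    ti_cols, tti_cols = [], []
    arity = {f.name: f.arity for f in FAMILIES}
    for _, row in best.iterrows():
        fam = row["family"]
        labels = tuple(x.strip() for x in row["combination"].split(","))
        col = f"{fam}_best"
        vals = materialize_index(fam, tfs, labels)
        if np.isnan(vals).any():
            fill = float(np.nanmedian(vals))
            vals = np.where(np.isnan(vals), fill, vals)
        features[col] = vals
        (ti_cols if arity[fam] == 2 else tti_cols).append(col)
    blocks = {"VIs": vi_sel, "TFs": tf_sel, "TIs": ti_cols, "TTIs": tti_cols}
    return features, blocks, best


# ---------------------------------------------------------------- stages

def run_simulate(config: RunConfig) -> tuple[list[PlotSample], pd.DataFrame]:
    outdir = Path(config.outdir)
    samples, truth = generate_experiment(
        config.design, config.effects, config.radiative,
        seed=config.generator_seed, outdir=outdir / "scenes",
    )
    _log_stage(config, "simulate", plots=len(samples))
    return samples, truth


def _load_samples(config: RunConfig) -> tuple[list[PlotSample], pd.DataFrame]:
    scenes = Path(config.outdir) / "scenes"
    truth = pd.read_csv(scenes / "truth.csv")
    missing = [
        pid for pid in truth["plot_id"]
        if not (scenes / f"{pid}.tif").exists() or not (scenes / f"{pid}_mask.tif").exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing scene rasters for plots: {missing}")
    samples = []
    for row in truth.itertuples(index=False):
        image = read_image(scenes / f"{row.plot_id}.tif")
        mask = read_mask(scenes / f"{row.plot_id}_mask.tif")
        samples.append(
            PlotSample(row.plot_id, int(row.season), row.mulching,
                       float(row.nitrogen_kg_hm2), float(row.true_lai), image, mask)
        )
    return samples, truth


def run_extract(
    config: RunConfig, samples: list[PlotSample] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    outdir = Path(config.outdir)
    if samples is None:
        samples, truth = _load_samples(config)
    else:
        truth = pd.read_csv(outdir / "scenes" / "truth.csv")
    vis, tfs = extract_features(samples, config)
    vis.to_csv(outdir / "vis.csv", float_format=_CSV_FLOAT)
    tfs.to_csv(outdir / "tfs.csv", float_format=_CSV_FLOAT)
    (outdir / "glcm_config.json").write_text(
        json.dumps(dataclasses.asdict(config.glcm), indent=2) + "\n"
    )
    _log_stage(config, "extract", rows=len(vis), vi_cols=vis.shape[1], tf_cols=tfs.shape[1])
    return vis, tfs, truth


def run_search(
    config: RunConfig,
    vis: pd.DataFrame | None = None,
    tfs: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    save_heatmaps: bool = True,
) -> dict:
    outdir = Path(config.outdir)
    if vis is None or tfs is None or truth is None:
        vis = pd.read_csv(outdir / "vis.csv", index_col="plot_id")
        tfs = pd.read_csv(outdir / "tfs.csv", index_col="plot_id")
        truth = pd.read_csv(outdir / "scenes" / "truth.csv")
    lai = truth.set_index("plot_id").loc[vis.index, "true_lai"].to_numpy()
    vi_screen = screen_table(screen_variables(vis, lai, config.alpha))
    tf_screen = screen_table(screen_variables(tfs, lai, config.alpha))
    vi_screen.to_csv(outdir / "vi_screen.csv", index=False, float_format=_CSV_FLOAT)
    tf_screen.to_csv(outdir / "tf_screen.csv", index=False, float_format=_CSV_FLOAT)
    tensors, rows = {}, []
    for fam in config.families:
        tensor, res = search_family(fam, tfs, lai)
        tensors[fam] = tensor
        rows.append(
            {
                "family": res.family,
                "abs_r": res.abs_r,
                "r": res.r,
                "p": res.p,
                "significant": res.p < 0.05,
                "combination": ", ".join(res.labels),
                "n_used": res.n_used,
            }
        )
    best = pd.DataFrame(rows)
    best.to_csv(outdir / "best_combinations.csv", index=False, float_format=_CSV_FLOAT)
    np.savez_compressed(
        outdir / "tensors.npz",
        **{fam: t.values for fam, t in tensors.items()},
        labels=np.array(tensors[config.families[0]].labels),
    )
    if save_heatmaps:
        _save_heatmaps(tensors, outdir)
    _log_stage(config, "search", families=len(best))
    return {"vi_screen": vi_screen, "tf_screen": tf_screen, "best": best,
            "tensors": tensors, "lai": lai, "vis": vis, "tfs": tfs}


def _save_heatmaps(tensors: dict, outdir: Path) -> None:
    """|r| search surfaces; 3-term families show the slice through the optimum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for fam, tensor in tensors.items():
        vals = tensor.values
        if vals.ndim == 3:
            flat = np.where(np.isfinite(vals), vals, -np.inf)
            k = np.unravel_index(int(np.argmax(flat)), vals.shape)[2]
            vals = vals[:, :, k]
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(vals, origin="lower", cmap="viridis", vmin=0, vmax=1)
        ax.set_title(f"{fam}: |r| with LAI")
        ax.set_xlabel("T_j feature index")
        ax.set_ylabel("T_i feature index")
        fig.colorbar(im, ax=ax, label="|r|")
        fig.savefig(outdir / f"heatmap_{fam}.png", dpi=110)
        plt.close(fig)


def run_model(
    config: RunConfig,
    search_out: dict | None = None,
    samples: list[PlotSample] | None = None,
) -> dict:
    outdir = Path(config.outdir)
    if search_out is None:
        vis = pd.read_csv(outdir / "vis.csv", index_col="plot_id")
        tfs = pd.read_csv(outdir / "tfs.csv", index_col="plot_id")
        truth = pd.read_csv(outdir / "scenes" / "truth.csv")
        best = pd.read_csv(outdir / "best_combinations.csv")
        lai = truth.set_index("plot_id").loc[vis.index, "true_lai"].to_numpy()
    else:
        vis, tfs, lai = search_out["vis"], search_out["tfs"], search_out["lai"]
        best = search_out["best"]
    features, blocks, best = resolve_feature_blocks(vis, tfs, lai, config, best)
    split = split_dataset(len(features), seed=config.split_seed)
    specs = default_model_specs(config.model_random_state)
    results = run_grid(features, lai, blocks, split, specs)
    table = grid_table(results)
    table.to_csv(outdir / "grid.csv", index=False, float_format=_CSV_FLOAT)
    # best validation cell → scatter data and an inversion map
    best_i = int(table["validation_R2"].idxmax())
    combo_name, model_name = table.loc[best_i, ["combination", "model"]]
    combos = {c.name: c for c in enumerate_combinations(blocks)}
    combo = combos[combo_name]
    spec = next(s for s in specs if s.name == model_name)
    X = features[combo.columns].to_numpy(dtype=np.float64)
    model = fit_model(spec, X[split.modeling], lai[split.modeling])
    model.combination = combo.name
    pred = model.predict(X)
    role = np.where(np.isin(np.arange(len(lai)), split.modeling), "modeling", "validation")
    scatter = pd.DataFrame(
        {"plot_id": features.index, "role": role, "true_lai": lai, "predicted_lai": pred}
    )
    scatter.to_csv(outdir / "scatter.csv", index=False, float_format=_CSV_FLOAT)
    map_path = None
    if samples is not None and len(split.validation):
        s = samples[int(split.validation[0])]
        arity = {f.name: f.arity for f in FAMILIES}
        tuples = {
            row["family"]: tuple(x.strip() for x in row["combination"].split(","))
            for _, row in best.iterrows()
        }
        lai_map = predict_map(s.image, s.vegetation_mask, model, combo,
                              best_tuples=tuples, glcm_config=config.glcm)
        import tifffile

        map_path = outdir / "lai_map.tif"
        tifffile.imwrite(map_path, lai_map.astype(np.float32))
    _log_stage(config, "model", cells=len(table), best=f"{combo_name}/{model_name}")
    return {"grid": table, "scatter": scatter, "best_cell": (combo_name, model_name),
            "features": features, "blocks": blocks, "split": split, "map_path": map_path}


def run_all(config: RunConfig) -> dict:
    """Full pipeline from one config; returns the model-stage outputs."""
    samples, truth = run_simulate(config)
    vis, tfs, truth = run_extract(config, samples)
    search_out = run_search(config, vis, tfs, truth)
    out = run_model(config, search_out, samples)
    out["truth"] = truth
    out["search"] = search_out
    return out
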