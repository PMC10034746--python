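"""End-to-end orchestration: generate -> ingest -> register -> extract ->
fit -> report, with config serialization, JSON-line logs, and a manifest.

Each stage writes its artifacts into the run directory and the whole run is
idempotent for a fixed seed (identical cell tables and metrics on re-run).
The demo configuration is a reduced-size control series (1,000 cells/day,
days 0-7) that exercises every stage.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cells as C
from . import models as M
from . import msi as X
from . import registration as R
from . import synthetic as S
from .transform import AffineTransform2D

ALL_STAGES = ("generate", "ingest", "register", "extract", "fit", "report")

STAGE_DEPS = {
    "ingest": ("generate",),
    "register": ("ingest",),
    "extract": ("register",),
    "fit": ("extract",),
    "report": ("fit",),
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str = "runs/demo"
    seed: int = 0
    n_cells: int = 1000
    days: tuple = tuple(range(8))
    condition: str = "control"
    stages: tuple = ALL_STAGES
    with_replicate: bool = True
    # registration search box (the demo phantom plants transforms well inside)
    reg_rotation_deg: float = 8.0
    reg_shift_px: float = 25.0
    reg_scale: float = 0.05
    # feature pipeline
    min_pixel_fraction: float = 0.01
    screen_threshold: float = 0.3
    n_features: int = 70

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            for dep in STAGE_DEPS.get(stage, ()):
                if dep not in self.stages:
                    raise ConfigError(
                        f"stage {stage!r} requires {dep!r} to be enabled")
        if self.condition not in S.CONDITIONS:
            raise ConfigError(f"condition must be one of {S.CONDITIONS}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["days"] = list(self.days)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        try:
            d["days"] = tuple(d.get("days", range(8)))
            d["stages"] = tuple(d.get("stages", ALL_STAGES))
            return cls(**d)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def phantom_config(self) -> S.ColonyPhantomConfig:
        return S.ColonyPhantomConfig(
            n_cells=self.n_cells, days=self.days, condition=self.condition,
            panel=S.default_panel(self.n_features), seed=self.seed)


def _log_line(run_dir: Path, record: dict) -> None:
    with open(run_dir / "run.log", "a") as fh:
        fh.write(json.dumps(record) + "\n")


def run(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    A stage failure halts the run with a :class:`StageError`; artifacts from
    completed stages are preserved.
    """
    config.validate()
    run_dir = Path(config.outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    manifest: dict = {"seed": config.seed, "stages": {}, "versions": _versions()}
    state: dict = {"config": config, "run_dir": run_dir}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](state)
        except Exception as e:
            _log_line(run_dir, {"stage": stage, "status": "failed", "error": str(e)})
            manifest["stages"][stage] = {"status": "failed", "error": str(e)}
            (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(f"stage {stage!r} failed: {e}") from e
        elapsed = time.perf_counter() - t0
        manifest["stages"][stage] = {"status": "ok",
                                     "elapsed_s": round(elapsed, 3)}
        _log_line(run_dir, {"stage": stage, "status": "ok",
                            "elapsed_s": round(elapsed, 3)})
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def _versions() -> dict:
    import sklearn, skimage, scipy
    import lipidcolony
    return {"lipidcolony": lipidcolony.__version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__, "pandas": pd.__version__}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _reps(config: RunConfig):
    return (0, 1) if config.with_replicate else (0,)


def _stage_generate(state: dict) -> None:
    config: RunConfig = state["config"]
    data_dir = state["run_dir"] / "data"
    phantom = config.phantom_config()
    paths: dict = {}
    truths: dict = {}
    for day in config.days:
        for rep in _reps(config):
            paths[(day, rep)] = S.export_colony(phantom, day, data_dir, rep)
        _, _, truth = S.generate_colony(phantom, day, 0)
        truths[day] = truth
    state["paths"] = paths
    state["truths"] = truths
    state["phantom"] = phantom


def _stage_ingest(state: dict) -> None:
    config: RunConfig = state["config"]
    datasets = {}
    for key, p in state["paths"].items():
        datasets[key] = X.read_imzml(p["imzml"],
                                     pixel_size=state["phantom"].msi_pitch)
    state["datasets"] = datasets


def _stage_register(state: dict) -> None:
    import tifffile
    config: RunConfig = state["config"]
    phantom: S.ColonyPhantomConfig = state["phantom"]
    reg_dir = state["run_dir"] / "registration"
    reg_dir.mkdir(exist_ok=True)
    results = {}
    ranges = R.SearchRanges(rotation_deg=config.reg_rotation_deg,
                            shift_px=config.reg_shift_px,
                            scale=config.reg_scale)
    for (day, rep), dataset in state["datasets"].items():
        confocal = tifffile.imread(state["paths"][(day, rep)]["confocal"])
        hoechst = confocal[0].astype(float)
        msi_ref = X.mean_ion_image(dataset)
        result = R.register(hoechst, msi_ref.values,
                            conf_pitch=phantom.confocal_pitch,
                            msi_pitch=phantom.msi_pitch,
                            ranges=ranges, seed=config.seed)
        if not result.converged:
            raise StageError(f"registration failed for day {day} rep {rep}")
        result.transform.to_json(reg_dir / f"day{day}_rep{rep}_transform.json")
        (reg_dir / f"day{day}_rep{rep}_result.json").write_text(json.dumps({
            "mi": result.mi, "converged": result.converged,
            "permutation_floor": result.permutation_floor,
            "params": result.transform.to_dict()}, indent=2))
        results[(day, rep)] = result
    state["registrations"] = results


def _stage_extract(state: dict) -> None:
    import tifffile
    config: RunConfig = state["config"]
    phantom: S.ColonyPhantomConfig = state["phantom"]
    tab_dir = state["run_dir"] / "tables"
    tab_dir.mkdir(exist_ok=True)
    tables: dict = {}
    featureset = None
    for (day, rep), dataset in sorted(state["datasets"].items()):
        if featureset is None:
            # features are picked once, from the first dataset, and screened
            # against its colony footprint (Otsu of the mean ion image)
            raw = X.pick_and_bin_peaks(dataset,
                                       min_pixel_fraction=config.min_pixel_fraction)
            images = X.build_ion_images(dataset, raw)
            from skimage.filters import threshold_otsu
            mean_img = X.mean_ion_image(dataset)
            mask = mean_img.values > threshold_otsu(mean_img.values)
            featureset = X.screen_features(raw, images, mask,
                                           threshold=config.screen_threshold)
            featureset.to_csv(state["run_dir"] / "features.csv")
        confocal = tifffile.imread(state["paths"][(day, rep)]["confocal"])
        nuclei = C.segment_nuclei(
            confocal[0].astype(float), phantom.confocal_pitch,
            fluor_imgs={"TRA181": confocal[1].astype(float),
                        "SSEA1": confocal[2].astype(float),
                        "NCAM1": confocal[3].astype(float)})
        transform = state["registrations"][(day, rep)].transform
        table = C.extract_cell_abundances(nuclei, transform, dataset,
                                          featureset, day=day,
                                          condition=config.condition)
        # spatial context in the confocal frame
        from skimage.filters import threshold_otsu as _otsu
        from scipy import ndimage as _ndi
        smoothed = _ndi.gaussian_filter(confocal[0].astype(float), 2.0)
        nuc_mask = smoothed > _otsu(smoothed)
        colony = C.colony_mask_from_nuclei(nuc_mask, phantom.confocal_pitch)
        table["edge_distance_um"] = C.edge_distance(
            table[["x_um", "y_um"]].to_numpy(), colony, phantom.confocal_pitch)
        table["mitotic"] = C.detect_mitotic(table, seed=config.seed)
        tables[(day, rep)] = table
        C.save_cell_table(table, tab_dir / f"day{day}_rep{rep}_cells")
    _write_column_dictionary(tab_dir, featureset)
    state["tables"] = tables
    state["featureset"] = featureset


def _write_column_dictionary(tab_dir: Path, featureset: X.FeatureSet) -> None:
    cols = {
        "cell_id": "nucleus id within its image",
        "x_um,y_um": "nuclear centroid, confocal frame (um)",
        "area_um2": "nuclear area (um^2)",
        "eccentricity": "nuclear ellipse eccentricity",
        "solidity": "area / convex area",
        "hoechst_mean": "mean Hoechst intensity under the nuclear mask",
        "tra181_mean,ssea1_mean,ncam1_mean": "mean marker fluorescence",
        "edge_distance_um": "distance to the colony boundary (um)",
        "mitotic": "2-means mitosis flag",
        "day": "day of spontaneous differentiation (0-7)",
        "condition": "culture condition",
    }
    cols.update({f"mz_{f.label}": f"mean ion abundance in "
                 f"[{f.interval[0]:.3f}, {f.interval[1]:.3f}] Th"
                 for f in featureset})
    (tab_dir / "columns.json").write_text(json.dumps(cols, indent=2))


def _stage_fit(state: dict) -> None:
    config: RunConfig = state["config"]
    fit_dir = state["run_dir"] / "models"
    fit_dir.mkdir(exist_ok=True)
    tables = state["tables"]
    train = pd.concat([t for (d, r), t in tables.items() if r == 0],
                      ignore_index=True)
    val = pd.concat([t for (d, r), t in tables.items() if r == 1],
                    ignore_index=True) if config.with_replicate else train
    feats = C.feature_columns(train)
    feats = [f for f in feats if f in val.columns]
    Xtr, ytr = train[feats].to_numpy(), train["day"].to_numpy()
    Xva, yva = val[feats].to_numpy(), val["day"].to_numpy()
    metrics: dict = {}

    if len(np.unique(ytr)) >= 2:
        n_comp = min(5, len(feats), len(train) - 1)
        plsr = M.fit_plsr(Xtr, ytr, Xva, yva, feats, n_components=n_comp)
        plsr.save_card(fit_dir / "plsr.json")
        metrics["plsr_validation_r2"] = plsr.metrics["validation_r2"]

        tree = M.fit_stage_tree(Xtr, ytr, Xva, yva, feats, seed=config.seed)
        _, _, acc3 = M.collapse_stages(tree.extra["y_val"], tree.extra["pred_val"])
        tree.metrics["validation_accuracy_3class"] = acc3
        importance = M.predictor_importance(tree)
        tree.metrics["predictor_importance"] = {
            k: round(v, 4) for k, v in sorted(importance.items(),
                                              key=lambda kv: -kv[1])[:8]}
        tree.save_card(fit_dir / "stage_tree.json")
        metrics["tree_validation_accuracy_8class"] = \
            tree.metrics["validation_accuracy_8class"]
        metrics["tree_validation_accuracy_3class"] = acc3

    # trajectory summaries + figure data
    days_present = np.sort(train["day"].unique())
    if len(days_present) >= 2:
        traj_rows = []
        for f in feats:
            s = M.trajectory_summary(
                train, f, covariate=S.OCT4_PERCENT_BY_DAY[list(days_present)])
            df = s["summary"]
            df["feature"] = f
            df["oct4_R"] = s["R"]
            traj_rows.append(df)
        pd.concat(traj_rows, ignore_index=True).to_csv(
            state["run_dir"] / "figures_data_trajectories.csv", index=False)

    edge_bins = C.bin_by_edge_distance(train, features=feats[:8])
    edge_bins.to_csv(state["run_dir"] / "figures_data_edge_bins.csv", index=False)

    day0 = train[train["day"] == train["day"].min()]
    div_rows = []
    if day0["mitotic"].nunique() == 2 and len(day0) > 25:
        for f in feats[:6]:
            rel = C.neighbor_relative_abundance(day0, f,
                                                k_neighbors=min(20, len(day0) - 1))
            cmp = C.compare_dividing(day0, f,
                                     k_neighbors=min(20, len(day0) - 1))
            div_rows.append({"feature": f, **{k: v for k, v in cmp.items()}})
        pd.DataFrame(div_rows).to_csv(
            state["run_dir"] / "figures_data_dividing.csv", index=False)
        metrics["dividing_tests"] = len(div_rows)

    # phenotype PLS-DA on the day where both marker arms are well expressed
    # (day 6 for control/PEMT runs; the final day under PI3K inhibition)
    if config.condition in ("control", "DZA_50uM") and 6 in config.days:
        late_day = 6
    else:
        late_day = max(config.days)
    late_tr = train[train["day"] == late_day]
    late_va = val[val["day"] == late_day]
    ch = ("tra181_mean", "ssea1_mean") if config.condition in ("control", "DZA_50uM") \
        else ("ssea1_mean", "ncam1_mean")
    names = tuple(c.split("_")[0].upper() for c in ch)
    if len(late_tr) > 10:
        labels_tr = M.label_by_kmeans(late_tr[list(ch)].to_numpy(), names,
                                      seed=config.seed)
        labels_va = M.label_by_kmeans(late_va[list(ch)].to_numpy(), names,
                                      seed=config.seed)
        plsda = M.trim_variables(late_tr[feats].to_numpy(), labels_tr,
                                 late_va[feats].to_numpy(), labels_va, feats)
        plsda.save_card(fit_dir / "plsda.json")
        metrics["plsda_validation_accuracy"] = \
            plsda.metrics.get("validation_accuracy")
        # biplot data
        kept = plsda.extra["kept_indices"]
        pd.DataFrame({
            "feature": [feats[i] for i in kept],
            "loading_1": plsda.loadings[:, 0],
            "loading_2": plsda.loadings[:, 1] if plsda.loadings.shape[1] > 1
            else 0.0,
        }).to_csv(state["run_dir"] / "figures_data_biplot.csv", index=False)

        # 3-population projection space
        day0_tr = train[train["day"] == train["day"].min()]
        pops = {"pluripotent_day0": day0_tr[feats].to_numpy()}
        for name in np.unique(labels_tr):
            pops[str(name)] = late_tr[feats].to_numpy()[labels_tr == name]
        if len(pops) >= 3 and all(len(v) > 2 for v in pops.values()):
            proj = M.build_projection_space(pops, feats)
            coords = proj.extra["project"](train[feats].to_numpy())
            proj_df = pd.DataFrame({"pc1": coords[:, 0], "pc2": coords[:, 1],
                                    "day": train["day"]})
            proj_df.to_csv(state["run_dir"] / "figures_data_projection.csv",
                           index=False)
            metrics["projection_pc1_day_spearman"] = M.day_pc1_spearman(
                proj.extra["project"], train, feats)

    (fit_dir / "metrics.json").write_text(json.dumps(metrics, indent=2,
                                                     default=float))
    state["metrics"] = metrics


def _stage_report(state: dict) -> None:
    report(state["run_dir"])


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def report(run_dir: str | Path) -> Path:
    """Render a Markdown report with figure panels from a completed run's
    artifacts; sections with missing artifacts are skipped with a notice."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    lines = ["# Colony lipidomics run report", ""]
    n_panels = 0

    def _panel(name: str, fn) -> None:
        nonlocal n_panels
        try:
            fig = fn()
        except FileNotFoundError:
            lines.append(f"*Section {name} skipped: artifact missing.*\n")
            return
        path = fig_dir / f"{name}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        lines.append(f"## {name}\n\n![{name}](figures/{name}.png)\n")
        n_panels += 1

    def trajectories():
        df = pd.read_csv(run_dir / "figures_data_trajectories.csv")
        feats = df["feature"].unique()[:8]
        fig, axes = plt.subplots(2, 4, figsize=(14, 6), sharex=True)
        for ax, f in zip(axes.ravel(), feats):
            sub = df[df["feature"] == f]
            ax.plot(sub["day"], sub["median"], "o-")
            ax.fill_between(sub["day"], sub["q25"], sub["q75"], alpha=0.3)
            ax.set_title(f, fontsize=9)
        fig.suptitle("Per-day median abundance (bands: 25th-75th pct)")
        return fig

    def edge_distance():
        df = pd.read_csv(run_dir / "figures_data_edge_bins.csv")
        fig, ax = plt.subplots(figsize=(7, 4))
        for f in df["feature"].unique()[:4]:
            sub = df[df["feature"] == f]
            ax.errorbar(sub["group"], sub["mean"],
                        yerr=[(sub["mean"] - sub["q25"]).clip(lower=0),
                              (sub["q75"] - sub["mean"]).clip(lower=0)],
                        label=f, marker="o", capsize=2)
        ax.set_xlabel("edge-distance group (100 um bins)")
        ax.set_ylabel("mean abundance")
        ax.legend(fontsize=7)
        return fig

    def biplot():
        df = pd.read_csv(run_dir / "figures_data_biplot.csv")
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.axhline(0, color="0.8"); ax.axvline(0, color="0.8")
        ax.scatter(df["loading_1"], df["loading_2"], s=12)
        for _, row in df.iterrows():
            ax.annotate(row["feature"].replace("mz_", ""),
                        (row["loading_1"], row["loading_2"]), fontsize=6)
        ax.set_xlabel("loading 1"); ax.set_ylabel("loading 2")
        ax.set_title("PLS-DA loadings")
        return fig

    def dividing():
        df = pd.read_csv(run_dir / "figures_data_dividing.csv")
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(range(len(df)), df["median_diff"])
        ax.set_xticks(range(len(df)))
        ax.set_xticklabels([f.replace("mz_", "") for f in df["feature"]],
                           rotation=45, fontsize=7)
        ax.set_ylabel("median diff (dividing - rest)")
        stars = ["*" if p is not None and p < 0.05 else "" for p in df["p_value"]]
        for i, s in enumerate(stars):
            ax.annotate(s, (i, df["median_diff"].iloc[i]), ha="center")
        return fig

    def projection():
        df = pd.read_csv(run_dir / "figures_data_projection.csv")
        fig, ax = plt.subplots(figsize=(6, 5))
        sc = ax.scatter(df["pc1"], df["pc2"], c=df["day"], s=4, cmap="coolwarm")
        fig.colorbar(sc, label="day")
        ax.set_xlabel("PC1 (time)"); ax.set_ylabel("PC2 (fate)")
        return fig

    def metrics_panel():
        p = run_dir / "models" / "metrics.json"
        if not p.exists():
            raise FileNotFoundError(p)
        metrics = json.loads(p.read_text())
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.axis("off")
        text = "\n".join(f"{k}: {v if not isinstance(v, float) else round(v, 3)}"
                         for k, v in metrics.items())
        ax.text(0.02, 0.95, text or "no metrics", va="top", family="monospace")
        return fig

    _panel("trajectories", trajectories)
    _panel("edge_distance", edge_distance)
    _panel("plsda_biplot", biplot)
    _panel("dividing_cells", dividing)
    _panel("projection_space", projection)
    _panel("model_metrics", metrics_panel)

    lines.append(f"\n*{n_panels} figure panel(s) rendered.*\n")
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "ingest": _stage_ingest,
    "register": _stage_register,
    "extract": _stage_extract,
    "fit": _stage_fit,
    "report": _stage_report,
}


def demo_config(outdir: str | Path, seed: int = 0, n_cells: int = 1000,
                days: tuple = tuple(range(8))) -> RunConfig:
    """The reduced-size demonstration configuration (control series)."""
    return RunConfig(outdir=str(outdir), seed=seed, n_cells=n_cells, days=days)
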