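"""End-to-end study orchestration.

``run_study`` executes the whole analysis from one seeded config: generate
(or load) a soil landscape and plot network, extract map attributes at the
plots, summarize and test the class–cation correspondence, fit the
stepwise-AIC cation models per dataset and variant, derive the edaphic
gradients, estimate weighted-averaging niches along each of them, compare
optima rankings against the field-measured reference, and combine the
per-dataset tolerance envelopes.  All randomness flows from the single root
seed through named substreams, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    PlotRecord,
    SoilMapStack,
    abundance_frame,
    frame_to_plots,
    plots_to_frame,
)
from .extraction import (
    ClassAggregationTable,
    aggregate_classes,
    extract_class_at_points,
    extract_raster_at_points,
)
from .landscape import (
    LandscapeConfig,
    SyntheticTruth,
    default_species,
    generate_landscape,
    sample_plots,
    simulate_abundances,
)
from .models import (
    GradientVector,
    RegressionFit,
    anova_tukey,
    class_cation_summary,
    fit_cation_model,
    pearson_corr,
    predict_cation,
)
from .niche import combine_envelopes, niche_table, rank_correlation

logger = logging.getLogger(__name__)

_STAGES = ("landscape", "plots", "abundances")


def derive_seed(root_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    ss = np.random.SeedSequence([root_seed, _stable_hash(stage), index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _stable_hash(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


@dataclass
class StudyConfig:
    """Configuration of one full study run.

    ``datasets`` maps dataset tag to plot count; ``abundance_datasets``
    names the subset with fern inventories.  ``variants`` are the model
    configurations as (source, include_cec) with source ``polygon``
    (dominant-class dummies) or ``probability`` (class-probability layers).
    """

    mode: str = "synthetic"  # synthetic | files
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    datasets: dict[str, int] = field(
        default_factory=lambda: {"UTU": 879, "PPBio": 326, "SOTERLAC": 300}
    )
    noise_sd: float = 0.1
    abundance_datasets: tuple[str, ...] = ("UTU", "PPBio")
    variants: tuple[tuple[str, bool], ...] = (
        ("polygon", False),
        ("polygon", True),
        ("probability", False),
        ("probability", True),
    )
    reference_gradient: str = "measured_log_cation"
    seed: int = 0
    output_dir: str | None = None
    write_stack: bool = False
    # file-mode inputs
    plots_csv: str | None = None
    abundances_csv: str | None = None
    stack_dir: str | None = None
    aggregation_csv: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if not self.variants:
            raise ValueError("at least one model variant is required")
        for ds, n in self.datasets.items():
            if n < 1:
                raise ValueError(f"dataset {ds} size must be >= 1")
        for source, _ in self.variants:
            if source not in ("polygon", "probability"):
                raise ValueError(f"unknown model source {source!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "landscape" in raw and isinstance(raw["landscape"], dict):
            ls = dict(raw["landscape"])
            if "extent" in ls:
                ls["extent"] = tuple(ls["extent"])
            if "class_cation_params" in ls and ls["class_cation_params"] is not None:
                ls["class_cation_params"] = tuple(tuple(p) for p in ls["class_cation_params"])
            raw["landscape"] = LandscapeConfig(**ls)
        if "variants" in raw:
            raw["variants"] = tuple((v[0], bool(v[1])) for v in raw["variants"])
        if "abundance_datasets" in raw:
            raw["abundance_datasets"] = tuple(raw["abundance_datasets"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["landscape"]["extent"] = list(d["landscape"]["extent"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class StudyReport:
    """All tables produced by one study run, plus bookkeeping."""

    config: StudyConfig
    class_summary: pd.DataFrame
    anova: dict[str, Any]
    tukey_p: pd.DataFrame
    pearson: tuple[float, float]
    models: pd.DataFrame
    fits: dict[tuple[str, str, bool], RegressionFit]
    niches: dict[str, pd.DataFrame]
    tau: pd.DataFrame
    envelopes: pd.DataFrame
    dropped: dict[str, int]
    truth: SyntheticTruth | None = None

    def write(self, directory: str | Path) -> None:
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        ff = "%.12g"
        self.class_summary.to_csv(out / "class_summary.csv", index=False, float_format=ff)
        self.tukey_p.to_csv(out / "tukey_p.csv", float_format=ff)
        self.models.to_csv(out / "models.csv", index=False, float_format=ff)
        pd.concat(
            [df.assign(niche_dataset=ds) for ds, df in self.niches.items()], ignore_index=True
        ).to_csv(out / "niches.csv", index=False, float_format=ff)
        self.tau.to_csv(out / "tau.csv", float_format=ff)
        self.envelopes.to_csv(out / "envelopes.csv", index=False, float_format=ff)
        report = {
            "seed": self.config.seed,
            "version": __version__,
            "anova": self.anova,
            "pearson_r": self.pearson[0],
            "pearson_p": self.pearson[1],
            "dropped": self.dropped,
            "n_model_rows": int(len(self.models)),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        lines = [f"seed={self.config.seed}", f"version={__version__}"] + [
            f"dropped[{k}]={v}" for k, v in sorted(self.dropped.items())
        ]
        (out / "run.log").write_text("\n".join(lines) + "\n")


def _class_dummies(dominant: pd.Series) -> pd.DataFrame:
    """One-hot dominant-class design, most frequent class as baseline."""
    counts = dominant.value_counts()
    dummies = pd.get_dummies(dominant, prefix="class", dtype=float)
    baseline = f"class_{counts.index[0]}"
    return dummies.drop(columns=[baseline])


def _load_inputs(
    config: StudyConfig,
) -> tuple[SoilMapStack, list[PlotRecord], pd.DataFrame, SyntheticTruth | None]:
    if config.mode == "synthetic":
        ls = dataclasses.replace(config.landscape, seed=derive_seed(config.seed, "landscape"))
        stack, truth = generate_landscape(ls)
        truth.species = default_species()
        plots: list[PlotRecord] = []
        for i, (ds, n) in enumerate(sorted(config.datasets.items())):
            plots += sample_plots(
                truth, n, config.noise_sd, derive_seed(config.seed, "plots", i), dataset=ds
            )
        ab_plots = [p for p in plots if p.dataset in config.abundance_datasets]
        abund = simulate_abundances(ab_plots, truth.species, derive_seed(config.seed, "abundances"))
        return stack, plots, abund, truth
    for name in ("plots_csv", "stack_dir"):
        if getattr(config, name) is None or not Path(getattr(config, name)).exists():
            raise FileNotFoundError(f"{name} is required in files mode")
    stack = SoilMapStack.read(config.stack_dir)
    plots = frame_to_plots(pd.read_csv(config.plots_csv))
    abund = (
        pd.read_csv(config.abundances_csv, index_col="plot_id")
        if config.abundances_csv
        else pd.DataFrame(index=pd.Index([p.plot_id for p in plots], name="plot_id"))
    )
    abund.index = abund.index.astype(str)
    return stack, plots, abund, None


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full study and return (optionally write) its report."""
    stack, plots, abund, truth = _load_inputs(config)
    table = (
        ClassAggregationTable.from_csv(config.aggregation_csv)
        if config.aggregation_csv
        else ClassAggregationTable.default()
    )

    pf = plots_to_frame(plots)
    dropped: dict[str, int] = {}

    # --- extraction -------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        detailed = extract_class_at_points(stack.polygons, plots)
    dominant = aggregate_classes(detailed, table)
    rast = extract_raster_at_points(stack, plots)
    data = pf.join(dominant).join(rast)
    dropped["no_polygon_cover"] = int(dominant.isna().sum())
    dropped["no_raster_cover"] = int(rast["cec"].isna().sum())

    # --- class-cation correspondence -------------------------------------
    cls_ok = data.dropna(subset=["dominant_class", "cation_cmolkg"])
    summary = class_cation_summary(cls_ok["dominant_class"], cls_ok["cation_cmolkg"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        at = anova_tukey(np.log(cls_ok["cation_cmolkg"]), cls_ok["dominant_class"])
    pear = pearson_corr(np.log(data["cation_cmolkg"]), data["cec"])

    # --- cation models per dataset grouping x variant ---------------------
    prob_names = list(stack.prob_layers)
    groupings: dict[str, pd.DataFrame] = {ds: data[data["dataset"] == ds] for ds in
                                          sorted(config.datasets)} if config.mode == "synthetic" else {
        ds: data[data["dataset"] == ds] for ds in sorted(data["dataset"].unique())
    }
    groupings["Combined"] = data
    fits: dict[tuple[str, str, bool], RegressionFit] = {}
    rows = []
    for gname, gdata in groupings.items():
        for source, use_cec in config.variants:
            if source == "probability":
                design = gdata[["cation_cmolkg", "cec"] + prob_names].copy()
                predictors = prob_names
            else:
                sub = gdata.dropna(subset=["dominant_class"])
                dummies = _class_dummies(sub["dominant_class"])
                design = pd.concat([sub[["cation_cmolkg", "cec"]], dummies], axis=1)
                predictors = list(dummies.columns)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cation_model(design, predictors, include_cec=use_cec)
            fits[(gname, source, use_cec)] = fit
            rows.append(
                {
                    "dataset": gname,
                    "source": source,
                    "cec": use_cec,
                    "aic": fit.aic,
                    "adj_r2": fit.adj_r2,
                    "p_value": fit.p_value,
                    "n": fit.n,
                    "n_selected": len(fit.selected),
                    "selected": "+".join(fit.selected),
                }
            )
    models = pd.DataFrame(rows)

    # --- gradients and niches ---------------------------------------------
    niche_groups = {ds: data[data["dataset"] == ds] for ds in config.abundance_datasets
                    if (data["dataset"] == ds).any()}
    if len(niche_groups) > 1:
        niche_groups["Both"] = data[data["dataset"].isin(config.abundance_datasets)]
    niches: dict[str, pd.DataFrame] = {}
    tau_rows = []
    for ds, gdata in niche_groups.items():
        fit_key = ds if ds in groupings else "Combined"
        grads = [
            GradientVector(np.log(gdata["cation_cmolkg"]), "measured_log_cation", "field samples"),
            GradientVector(gdata["cec"], "cec", "CEC raster, untransformed"),
        ]
        for source, use_cec in config.variants:
            fit = fits[(fit_key, source, use_cec)]
            if source == "probability":
                nd = gdata[["cec"] + prob_names]
            else:
                # full one-hot set (no baseline drop): whatever dummies the
                # per-group fit selected are guaranteed to be present
                dummies = pd.get_dummies(
                    data["dominant_class"].dropna(), prefix="class", dtype=float
                )
                nd = pd.concat(
                    [gdata[["cec"]], dummies.reindex(gdata.index, fill_value=0.0)], axis=1
                )
                nd = nd.reindex(columns=list(nd.columns) + [c for c in fit.selected
                                                            if c not in nd.columns], fill_value=0.0)
            gid = f"predicted({source}{'+cec' if use_cec else ''})"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                grads.append(predict_cation(fit, nd, gradient_id=gid))
        ab = abund.reindex([p for p in gdata.index if p in abund.index]).fillna(0)
        nt = niche_table(ab, grads, reference=config.reference_gradient)
        niches[ds] = nt
        ref = nt[nt["gradient_id"] == config.reference_gradient].set_index("taxon")["optimum"]
        for gid in nt["gradient_id"].unique():
            if gid == config.reference_gradient:
                continue
            other = nt[nt["gradient_id"] == gid].set_index("taxon")["optimum"]
            cmp_res = rank_correlation(ref, other, config.reference_gradient, gid)
            tau_rows.append({"dataset": ds, "gradient": gid, "tau": cmp_res.tau,
                             "p_value": cmp_res.p_value, "n_taxa": cmp_res.n_taxa})
    tau = pd.DataFrame(tau_rows)
    if not tau.empty:
        tau = tau.pivot(index="dataset", columns="gradient", values="tau")

    # --- combined envelopes (measured gradient, per-dataset) --------------
    per_ds = {
        ds: niches[ds][niches[ds]["gradient_id"] == config.reference_gradient]
        for ds in config.abundance_datasets
        if ds in niches
    }
    env = combine_envelopes(per_ds)
    env_df = pd.DataFrame(
        [
            {"taxon": e.taxon, "lower": e.lower, "upper": e.upper,
             **{f"optimum_{ds}": u for ds, u in e.optima.items()}}
            for e in env
        ]
    )

    report = StudyReport(
        config=config,
        class_summary=summary,
        anova={"F": at.f_statistic, "p": at.p_value, "df": list(at.df)},
        tukey_p=at.tukey_p,
        pearson=pear,
        models=models,
        fits=fits,
        niches=niches,
        tau=tau,
        envelopes=env_df,
        dropped=dropped,
        truth=truth,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        report.write(out)
        plots_to_frame(plots).to_csv(out / "plots.csv", float_format="%.12g")
        abund.to_csv(out / "abundances.csv")
        if config.write_stack:
            stack.write(out / "stack")
    return report


def validate_inputs(
    stack: SoilMapStack | None = None,
    plots: Sequence[PlotRecord] | pd.DataFrame | None = None,
    abundances: pd.DataFrame | None = None,
    taxa: Sequence[str] | None = None,
) -> list[dict[str, str]]:
    """Check inputs for common defects; returns a machine-readable issue list.

    Never raises: every problem becomes one ``{"issue": ..., "detail": ...}``
    entry, and an empty list means no problems were found.
    """
    issues: list[dict[str, str]] = []
    if stack is not None:
        specs = {layer.spec for layer in stack.prob_layers.values()}
        if len(specs | {stack.cec.spec}) > 1:
            issues.append({"issue": "grid mismatch", "detail": "rasters are not on one grid"})
        for name, layer in stack.prob_layers.items():
            v = layer.data[np.isfinite(layer.data)]
            if v.size and (v.min() < 0 or v.max() > 1):
                issues.append({"issue": "probability out of range", "detail": name})
        total = sum(np.nan_to_num(l.data) for l in stack.prob_layers.values())
        if stack.prob_layers and np.nanmax(total) > 1 + 1e-9:
            issues.append({"issue": "probabilities sum above 1", "detail": f"max={np.nanmax(total):.3f}"})
    if plots is not None:
        pf = plots if isinstance(plots, pd.DataFrame) else plots_to_frame(plots)
        if "cation_cmolkg" in pf.columns:
            bad = pf["cation_cmolkg"].dropna() <= 0
            if bad.any():
                issues.append(
                    {"issue": "non-positive cation", "detail": f"{int(bad.sum())} plots"}
                )
        if stack is not None:
            _, _, inside = stack.spec.index_of(pf["x"].to_numpy(), pf["y"].to_numpy())
            if (~inside).any():
                issues.append(
                    {"issue": "plots outside raster extent", "detail": f"{int((~inside).sum())} plots"}
                )
    if abundances is not None:
        if (abundances.to_numpy(float) < 0).any():
            issues.append({"issue": "negative abundance", "detail": "counts must be >= 0"})
        if taxa is not None:
            extra = sorted(set(abundances.columns) - set(taxa))
            if extra:
                issues.append({"issue": "unknown taxa", "detail": ", ".join(extra)})
    return issues
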