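"""End-to-end runs: staged pipeline execution and reference-data reproduction.

Two entry points:

- :func:`run_pipeline` executes a configured sequence of stages (``simulate``,
  ``hrma``, ``taqman``, ``repair``, ``ngs``) on files or synthetic inputs,
  writing tidy CSV outputs plus a JSON manifest (parameters, seeds, package
  version) so a rerun with the same config is byte-identical in its values.
- :func:`reproduce_reference_results` refits the packaged PCR-product mix
  calibration series (both standard curves), re-derives every re-estimated
  percentage column including the cross-applications, and recomputes the
  repair-partition table from the packaged probe panels, returning
  side-by-side comparisons with absolute deviations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import melt, ngs, repair, synthetic, taqman
from .errors import EditQuantError

__all__ = ["RunConfig", "run_pipeline", "reproduce_reference_results", "ReferenceComparison"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "hrma", "taqman", "repair", "ngs")


def _load_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("editquant").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


@dataclass
class RunConfig:
    """Configuration for a staged pipeline run.

    Only the fields used by the requested stages need to be set.  ``seed``
    feeds every synthetic stage; all seeds and parameters are recorded in the
    output manifest.
    """

    stages: tuple[str, ...]
    out_dir: Path
    seed: int = 0
    # hrma
    melt_csv: Path | None = None  # wide melt CSV; generated by `simulate` if absent
    window: tuple[float, float] | None = None
    control_label: str | None = None
    orientation: str = "dca-from-pct"
    calibration_fractions: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 11))
    # taqman
    cq_csv: Path | None = None
    dilution_csv: Path | None = None
    reference_target: str = "reference"
    # repair
    panel_csv: Path | None = None
    # ngs
    locus_yaml: Path | None = None
    reads_path: Path | None = None
    stringency: int | None = None

    def validate(self) -> None:
        problems = []
        if not self.stages:
            problems.append("stages: empty stage list")
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            problems.append(f"stages: unknown stage(s) {unknown}; valid: {list(_STAGES)}")
        if "hrma" in self.stages and "simulate" not in self.stages and self.melt_csv is None:
            problems.append("melt_csv: required for the hrma stage without simulate")
        if "taqman" in self.stages and "simulate" not in self.stages and self.cq_csv is None:
            problems.append("cq_csv: required for the taqman stage without simulate")
        if "repair" in self.stages and self.panel_csv is None:
            problems.append("panel_csv: required for the repair stage")
        if "ngs" in self.stages and (self.locus_yaml is None or
                                     ("simulate" not in self.stages and self.reads_path is None)):
            problems.append("locus_yaml/reads_path: required for the ngs stage")
        for name in ("melt_csv", "cq_csv", "dilution_csv", "panel_csv",
                     "locus_yaml", "reads_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name}: file not found: {p}")
        if problems:
            raise EditQuantError("invalid run config: " + "; ".join(problems))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in canonical order; return the manifest.

    Outputs land under ``config.out_dir``; the manifest (also written to
    ``manifest.json``) records the package version, the config, and each
    stage's headline numbers.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    sim_products: dict = {}
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        runner = globals()[f"_stage_{stage}"]
        manifest["stages"][stage] = runner(config, out, sim_products)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    lines = [f"editquant run (seed {config.seed})"]
    for stage, info in manifest["stages"].items():
        lines.append(f"  {stage}: " + ", ".join(f"{k}={v}" for k, v in info.items()
                                                if not isinstance(v, (dict, list))))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return manifest


def _stage_simulate(config: RunConfig, out: Path, products: dict) -> dict:
    """Synthesize melt mixtures, a Cq panel and a dilution series."""
    grid = synthetic.default_temperature_grid()
    wt = synthetic.MeltModelParams(tm=78.5)
    mut = synthetic.MeltModelParams(tm=77.0)
    fracs = list(config.calibration_fractions)
    curves = [synthetic.simulate_mixture(f, wt, mut, grid, seed=config.seed + i,
                                         label=f"mix_{100 * f:g}")
              for i, f in enumerate(fracs)]
    df = pd.DataFrame({"Temperature": grid})
    for c in curves:
        df[c.label] = c.rfu
    melt_csv = out / "simulated_melt.csv"
    df.to_csv(melt_csv, index=False)
    products["melt_csv"] = melt_csv
    products["fractions"] = fracs
    products["control_label"] = curves[0].label
    # manifest records output names (not absolute paths) so reruns compare equal

    cq = synthetic.simulate_cq(synthetic.CqSimSpec(
        true_template_fractions={"control": 1.0, "edited_a": 0.32, "edited_b": 0.49},
        seed=config.seed,
    ))
    cq_csv = out / "simulated_cq.csv"
    cq.to_csv(cq_csv, index=False)
    products["cq_csv"] = cq_csv
    return {"melt_csv": melt_csv.name, "cq_csv": cq_csv.name, "n_mixes": len(fracs)}


def _stage_hrma(config: RunConfig, out: Path, products: dict) -> dict:
    """Normalize curves, compute DCAs against the control, fit the standard curve."""
    melt_csv = products.get("melt_csv", config.melt_csv)
    curves = melt.read_melt_csv(melt_csv)
    window = (melt.AnalysisWindow(*config.window) if config.window
              else melt.suggest_window(curves))
    normed = {c.label: melt.normalize_melt_curve(c, window) for c in curves}
    control_label = config.control_label or products.get("control_label") or curves[0].label
    control = normed[control_label]
    rows = []
    for label, nc in normed.items():
        rows.append((label, melt.difference_curve(nc, control).dca))
    dca_df = pd.DataFrame(rows, columns=["sample", "dca"])
    dca_df.to_csv(out / "hrma_dca.csv", index=False)

    info: dict = {"window": [window.t_low, window.t_high], "control": control_label,
                  "n_curves": len(curves)}
    fracs = products.get("fractions")
    if fracs is not None:  # calibration run: nominal percentages are known
        points = [(100.0 * f, d) for f, (_, d) in zip(fracs, rows)]
        std = melt.fit_standard_curve(points, config.orientation)
        std.to_json(out / "standard_curve.json")
        est = [melt.estimate_mutant_fraction(std, d).percent for _, d in rows]
        pd.DataFrame({"nominal_pct": [p for p, _ in points],
                      "dca": [d for _, d in points],
                      "estimated_pct": est}).to_csv(out / "hrma_estimates.csv", index=False)
        info["r_squared"] = std.r_squared
    return info


def _stage_taqman(config: RunConfig, out: Path, products: dict) -> dict:
    """Relative quantities for every sample against the control sample."""
    cq_csv = products.get("cq_csv", config.cq_csv)
    df = taqman.read_cq_csv(cq_csv)
    if config.dilution_csv is not None:
        e_t = taqman.fit_efficiency(
            taqman.read_dilution_csv(config.dilution_csv, "target")).efficiency
        e_r = taqman.fit_efficiency(
            taqman.read_dilution_csv(config.dilution_csv, config.reference_target)).efficiency
    else:
        e_t = e_r = 2.0
    control_label = config.control_label or "control"
    stats = {
        (s, t): taqman.cq_stats(grp["cq"]) for (s, t), grp in df.groupby(["sample", "target"])
    }
    control_cq = {"target": stats[(control_label, "target")],
                  "reference": stats[(control_label, config.reference_target)]}
    quantities = []
    for sample in df["sample"].unique():
        sample_cq = {"target": stats[(sample, "target")],
                     "reference": stats[(sample, config.reference_target)]}
        quantities.append(taqman.relative_quantity(sample, sample_cq, control_cq, e_t, e_r))
    quantities = taqman.normalize_panel(quantities, control_label)
    qdf = pd.DataFrame({"sample": [q.label for q in quantities],
                        "ratio": [q.ratio for q in quantities],
                        "sd": [q.sd for q in quantities]})
    qdf.to_csv(out / "taqman_quantities.csv", index=False)
    return {"e_target": e_t, "e_reference": e_r, "n_samples": len(quantities)}


def _stage_repair(config: RunConfig, out: Path, products: dict) -> dict:
    panels = repair.read_panel_csv(config.panel_csv)
    estimates = [repair.estimate_repair(p) for p in panels]
    repair.estimates_to_frame(estimates).to_csv(out / "repair_estimates.csv", index=False)
    return {"n_conditions": len(estimates)}


def _stage_ngs(config: RunConfig, out: Path, products: dict) -> dict:
    locus = ngs.LocusConfig.from_file(config.locus_yaml)
    if config.stringency is not None:
        locus = dataclasses.replace(locus, stringency=config.stringency)
    if config.reads_path is not None:
        reads = ngs.read_sequences(config.reads_path)
    else:  # simulate stage present: generate a small demonstration read set
        reads, _ = synthetic.simulate_reads(synthetic.ReadSimSpec(
            locus=locus,
            mutant_alleles=(synthetic.IndelAllele(position=len(locus.wild_type) // 2,
                                                  size=8, frequency=0.2),),
            n_reads=2000, seed=config.seed))
    summary = ngs.summarize_mutations(reads, locus)
    ngs.write_summary(summary, out / "ngs")
    return {"locus": locus.name, "percent_mutant": summary.percent_mutant,
            "with_target": summary.with_target}


@dataclass(frozen=True)
class ReferenceComparison:
    """Recomputed vs published values for the packaged reference datasets."""

    calibration: pd.DataFrame  # per-row re-estimates for all four % columns
    fit_stats: dict  # r_squared per mix series, MAD per estimation column
    repair_table: pd.DataFrame  # recomputed repair partition vs published
    max_abs_dev_calibration: float
    max_abs_dev_repair: float


def reproduce_reference_results(orientation: str = "dca-from-pct") -> ReferenceComparison:
    """Refit both packaged standard curves and recompute every derived column.

    Fits the two mix series (surrogate-mutant and authentic-mutant), applies
    each curve to its own and to the other series' DCAs, and recomputes the
    repair-partition table from the probe panels, comparing everything
    against the published values carried in the fixtures.
    """
    cal = _load_packaged_csv("hrma_mix_calibration.csv")
    nominal = cal["nominal_pct"].to_numpy(float)
    curves = {
        name: melt.fit_standard_curve(zip(nominal, cal[f"dca_{name}"]), orientation)
        for name in ("s3wt", "s2mt")
    }

    def estimates(curve_name: str, dca_col: str) -> np.ndarray:
        std = curves[curve_name]
        return np.array([melt.estimate_mutant_fraction(std, d).percent
                         for d in cal[dca_col]])

    recomputed = {
        "pct_s3wt_self": estimates("s3wt", "dca_s3wt"),
        "pct_s2mt_self": estimates("s2mt", "dca_s2mt"),
        "pct_s3wt_curve_on_s2mt": estimates("s3wt", "dca_s2mt"),
        "pct_s2mt_curve_on_s3wt": estimates("s2mt", "dca_s3wt"),
    }
    comp = cal[["nominal_pct"]].copy()
    max_dev = 0.0
    fit_stats: dict = {f"r_squared_{n}": c.r_squared for n, c in curves.items()}
    for col, est in recomputed.items():
        comp[f"{col}_published"] = cal[col]
        comp[f"{col}_recomputed"] = est
        comp[f"{col}_abs_dev"] = np.abs(est - cal[col].to_numpy(float))
        max_dev = max(max_dev, float(comp[f"{col}_abs_dev"].max()))
        fit_stats[f"mad_{col}"] = float(np.mean(np.abs(est - nominal)))

    panels_df = _load_packaged_csv("repair_probe_panels.csv")
    rep_rows = []
    max_dev_rep = 0.0
    for _, row in panels_df.iterrows():
        est = repair.estimate_repair(repair.ProbePanel(
            row["condition"], row["Ec"], row["Eb"], row["Ed_hom"], row["Ed_het"]))
        for name, got, ref in (("N", est.n, row["ref_N"]),
                               ("HN", est.hn, row["ref_HN"]),
                               ("HDR_a", est.hdr_a, row["ref_HDR_a"]),
                               ("HDR_t", est.hdr_t, row["ref_HDR_t"]),
                               ("pct_HDR_t", est.pct_hdr_t, row["ref_pct_HDR_t"])):
            # published values are rounded to 2 decimals; compare on that scale
            dev = abs(round(got, 2) - ref)
            rep_rows.append((row["condition"], name, got, ref, dev))
            max_dev_rep = max(max_dev_rep, dev)
    rep_df = pd.DataFrame(rep_rows, columns=["condition", "quantity", "recomputed",
                                             "published", "abs_dev"])
    return ReferenceComparison(comp, fit_stats, rep_df, max_dev, max_dev_rep)
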