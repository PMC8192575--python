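"""Run orchestration: QC accounting, config, end-to-end cohort analysis.

A run ties the three layers together: simulate (or load) per-subject imaging
inputs, extract the 25 regional measurements per subject, join them to the
risk-factor table, and run the statistical battery — a MANCOVA contrasting
the fetal-PCA anatomical variant against normal anatomy (all subjects), three
PLSR models with leave-one-out component selection and jackknife inference
(variant subjects excluded), and sex-specific age-quantile curves.

Everything stochastic flows from one integer seed; re-running a config
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .morphometry import extract_measurements
from .phantom import (
    ARTERY_RADIUS_NAMES,
    DENSITY_NAMES,
    MEASUREMENT_NAMES,
    PREDICTOR_NAMES,
    TERRITORY_RADIUS_NAMES,
    CohortSimSpec,
    make_cohort,
    make_tube_phantom,
    standard_phantom_spec,
)
from .stats import jackknife_pvalues, loo_cv, mancova, quantile_loess
from .volumes import GridSpec

__all__ = ["QCReport", "RunConfig", "qc_accounting", "run_cohort", "RESPONSE_SETS"]

log = logging.getLogger("vesselmorph")

#: The three PLSR response sets fitted per run.
RESPONSE_SETS = {
    "density": DENSITY_NAMES,
    "territory_radius": TERRITORY_RADIUS_NAMES,
    "artery_radius": ARTERY_RADIUS_NAMES,
}


def _pct(x: float) -> float:
    """Percentage rounded half-up to one decimal, presentation style."""
    return float(Decimal(100 * x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# --- QC accounting -----------------------------------------------------------

@dataclass
class QCReport:
    """Bookkeeping of dataset exclusions and the anatomical-variant split."""

    initial: int
    exclusions: dict[str, int]
    final: int
    variant_count: int
    variant_pct: float
    normal_count: int
    normal_pct: float

    def as_dict(self) -> dict:
        return {
            "initial": self.initial,
            "exclusions": dict(self.exclusions),
            "final": self.final,
            "variant_count": self.variant_count,
            "variant_pct": self.variant_pct,
            "normal_count": self.normal_count,
            "normal_pct": self.normal_pct,
        }


def qc_accounting(
    initial: int, exclusions: dict[str, int], variant_count: int
) -> QCReport:
    """Exclusion arithmetic: final = initial - sum(exclusions); the variant
    fraction is reported against the final count, rounded to one decimal."""
    if initial < 0 or variant_count < 0 or any(v < 0 for v in exclusions.values()):
        raise ValueError("all QC counts must be non-negative")
    total_excl = sum(exclusions.values())
    if total_excl > initial:
        raise ValueError(
            f"exclusions ({total_excl}) exceed the initial count ({initial})"
        )
    final = initial - total_excl
    if variant_count > final:
        raise ValueError(
            f"variant count ({variant_count}) exceeds the final count ({final})"
        )
    return QCReport(
        initial=initial,
        exclusions=dict(exclusions),
        final=final,
        variant_count=variant_count,
        variant_pct=_pct(variant_count / final) if final else 0.0,
        normal_count=final - variant_count,
        normal_pct=_pct((final - variant_count) / final) if final else 0.0,
    )


# --- Run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input mode: ``simulate`` (phantom + cohort simulation) or
    ``inputs`` (paths to real volumes and a factor table).  See
    ``RunConfig.from_yaml`` for the file schema.
    """

    out_dir: str | Path
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    atlas_threshold: float = 0.01
    k_max: int = 9
    loess_span: float = 0.75
    curve_measurements: list[str] | None = None
    make_plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be given")
        if not 0.0 < self.atlas_threshold < 1.0:
            raise ValueError(f"atlas_threshold must be in (0,1), got {self.atlas_threshold}")
        if not 1 <= self.k_max <= len(PREDICTOR_NAMES):
            raise ValueError(f"k_max must be in [1, 9], got {self.k_max}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def as_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "atlas_threshold": self.atlas_threshold,
            "k_max": self.k_max,
            "loess_span": self.loess_span,
            "curve_measurements": self.curve_measurements,
            "make_plots": self.make_plots,
        }


# --- Stages ------------------------------------------------------------------

def _simulate_measurements(cfg: RunConfig, rng_seed: int) -> tuple[pd.DataFrame, dict]:
    """Generate factors + phantom-measured morphometry for every subject."""
    sim = dict(cfg.simulate or {})
    n = int(sim.get("n_subjects", 20))
    grid = GridSpec(
        shape=tuple(sim.get("grid_shape", (40, 40, 40))),
        spacing=tuple(sim.get("grid_spacing", (1.0, 1.0, 1.0))),
    )
    cohort_spec = CohortSimSpec(
        n_subjects=n,
        fetal_pca_fraction=float(sim.get("fetal_pca_fraction", 0.125)),
        seed=rng_seed,
    )
    factors = make_cohort(cohort_spec)
    factors = factors[["subject"] + PREDICTOR_NAMES + ["fetal_pca"]]

    ss = np.random.SeedSequence(rng_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    rows = []
    hashes = {}
    for i in range(n):
        fetal = bool(factors.loc[i, "fetal_pca"])
        spec = standard_phantom_spec(
            grid=grid,
            seed=child_seeds[i],
            fetal_pca=fetal,
            radius_jitter=float(sim.get("radius_jitter", 0.04)),
            noise_voxel_count=int(sim.get("noise_voxel_count", 0)),
        )
        ph = make_tube_phantom(spec)
        hashes[f"subject_{i:04d}_mask"] = hashlib.sha256(
            ph.mask.data.tobytes()
        ).hexdigest()
        log.info("subject=%d stage=phantom fetal=%s fg=%d", i, fetal, ph.mask.foreground_count)
        meas = extract_measurements(
            ph.mask, ph.prob_atlas, ph.territories, ph.artery_masks, ph.icv_mask,
            threshold=cfg.atlas_threshold,
        )
        log.info("subject=%d stage=measure missing=%d", i, len(meas.missing))
        rows.append({"subject": i, **meas.as_dict()})
    meas_df = pd.DataFrame(rows)
    # phantom geometry does not depend on the risk factors; ICV from the
    # simulated cohort replaces the toy-ellipsoid value so the predictor is
    # on a human scale
    table = factors.merge(meas_df.drop(columns=["icv_cm3"]), on="subject")
    table["icv_cm3"] = factors["icv_cm3"]
    return table, hashes


def _load_measurements(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Measure every subject listed in the factor table from NIfTI volumes."""
    from .volumes import load_binary, load_labels, load_probability

    inputs = dict(cfg.inputs or {})
    table = pd.read_csv(inputs["table"])
    atlas = load_probability(inputs["atlas"])
    territories = load_labels(inputs["territories"], _territory_names(inputs))
    arteries = load_labels(inputs["arteries"], _artery_names(inputs))
    rows = []
    hashes = {}
    for _, rec in table.iterrows():
        sid = rec["subject"]
        mask = load_binary(str(inputs["mask_pattern"]).format(subject=sid))
        icv = load_binary(str(inputs["icv_pattern"]).format(subject=sid))
        hashes[f"subject_{sid}_mask"] = hashlib.sha256(mask.data.tobytes()).hexdigest()
        meas = extract_measurements(
            mask, atlas, territories, arteries, icv, threshold=cfg.atlas_threshold
        )
        log.info("subject=%s stage=measure missing=%d", sid, len(meas.missing))
        rows.append({"subject": sid, **meas.as_dict()})
    meas_df = pd.DataFrame(rows)
    return table.merge(meas_df, on="subject"), hashes


def _territory_names(inputs: dict) -> dict[int, str] | None:
    raw = inputs.get("territory_labels")
    return {int(k): v for k, v in raw.items()} if raw else None


def _artery_names(inputs: dict) -> dict[int, str] | None:
    raw = inputs.get("artery_labels")
    return {int(k): v for k, v in raw.items()} if raw else None


def _fit_response_set(
    table: pd.DataFrame, responses: list[str], k_max: int
) -> tuple[pd.DataFrame, int, np.ndarray]:
    """Listwise-delete, select k by LOO-CV, jackknife at the chosen k."""
    cols = PREDICTOR_NAMES + responses
    complete = table.dropna(subset=cols)
    dropped = len(table) - len(complete)
    if dropped:
        log.info("stage=plsr listwise_dropped=%d", dropped)
    X = complete[PREDICTOR_NAMES].to_numpy(dtype=float)
    Y = complete[responses].to_numpy(dtype=float)
    cv = loo_cv(X, Y, k_max)
    jk = jackknife_pvalues(
        X, Y, cv.chosen_k,
        predictor_names=PREDICTOR_NAMES, response_names=responses,
    )
    tab = jk.to_frame()
    return tab, cv.chosen_k, cv.rmse[cv.chosen_k - 1], len(complete)


def _beta_table(tab: pd.DataFrame, responses: list[str], rmse: np.ndarray) -> pd.DataFrame:
    """Wide layout: one row per predictor, one column per response, with a
    leading RMSE row and significance marks alongside each coefficient."""
    wide = tab.pivot(index="predictor", columns="response", values="beta")
    wide = wide.loc[PREDICTOR_NAMES, responses]
    pmat = tab.pivot(index="predictor", columns="response", values="p").loc[
        PREDICTOR_NAMES, responses
    ]
    out = pd.DataFrame(index=["RMSE"] + PREDICTOR_NAMES, columns=responses, dtype=object)
    out.loc["RMSE"] = [f"{v:.4f}" for v in rmse]
    for pred in PREDICTOR_NAMES:
        row = []
        for resp in responses:
            b, p = wide.loc[pred, resp], pmat.loc[pred, resp]
            mark = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            row.append(f"{b:+.4f}{mark}")
        out.loc[pred] = row
    out.index.name = "predictor"
    return out


def run_cohort(config: RunConfig) -> Path:
    """Execute a full run and write all outputs into the output directory.

    Outputs: ``cohort.csv`` (factors + 25 measurements), ``measurements.csv``,
    three ``plsr_<set>.csv`` beta tables plus ``plsr_<set>_long.csv`` with
    exact p-values, ``mancova.json``, ``adjusted_means.csv``, ``curves.csv``,
    ``qc_report.json`` and ``manifest.json``.  The anatomical-variant group is
    part of the MANCOVA but excluded from PLSR and the quantile curves.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        table, hashes = _simulate_measurements(config, config.seed)
    else:
        table, hashes = _load_measurements(config)

    table.to_csv(out / "cohort.csv", index=False, float_format="%.10g")
    table[["subject"] + MEASUREMENT_NAMES + ["icv_cm3"]].to_csv(
        out / "measurements.csv", index=False, float_format="%.10g"
    )

    n_total = len(table)
    variant = table["fetal_pca"].astype(bool)
    qc = qc_accounting(n_total, {}, int(variant.sum()))
    (out / "qc_report.json").write_text(json.dumps(qc.as_dict(), indent=2) + "\n")

    # MANCOVA: variant vs normal on all 24 measurements, all subjects
    mancova_payload: dict
    complete24 = table.dropna(subset=MEASUREMENT_NAMES + ["age_years", "sex"])
    if variant.sum() == 0 or variant.all():
        log.warning("stage=mancova skipped: only one anatomy group present")
        mancova_payload = {"skipped": True, "reason": "only one anatomy group present"}
    elif len(complete24) <= len(MEASUREMENT_NAMES) + 3:
        reason = (
            f"too few complete rows ({len(complete24)}) for "
            f"{len(MEASUREMENT_NAMES)} responses"
        )
        log.warning("stage=mancova skipped: %s", reason)
        mancova_payload = {"skipped": True, "reason": reason}
    else:
        res = mancova(
            complete24[MEASUREMENT_NAMES],
            complete24["fetal_pca"].to_numpy(),
            complete24[["age_years", "sex"]].to_numpy(),
        )
        res.adjusted_means.to_csv(out / "adjusted_means.csv", index=False, float_format="%.10g")
        mancova_payload = {
            "skipped": False,
            "n_rows": int(len(complete24)),
            "wilks_lambda": res.wilks_lambda,
            "f_value": res.f_value,
            "df_num": res.df_num,
            "df_den": res.df_den,
            "p_value": res.p_value,
            "bonferroni_n": res.bonferroni_n,
            "posthoc": res.posthoc.to_dict(orient="records"),
        }
    (out / "mancova.json").write_text(json.dumps(mancova_payload, indent=2) + "\n")

    # PLSR on the normal-anatomy subjects only
    normal = table.loc[~variant].reset_index(drop=True)
    log.info("stage=plsr n_normal=%d n_variant_excluded=%d", len(normal), int(variant.sum()))
    chosen = {}
    for set_name, responses in RESPONSE_SETS.items():
        tab, k, rmse, n_rows = _fit_response_set(normal, responses, config.k_max)
        chosen[set_name] = {"chosen_k": k, "n_rows": n_rows}
        _beta_table(tab, responses, rmse).to_csv(out / f"plsr_{set_name}.csv")
        tab.to_csv(out / f"plsr_{set_name}_long.csv", index=False, float_format="%.10g")
        log.info("stage=plsr set=%s chosen_k=%d", set_name, k)

    # sex-specific age-quantile curves on the normal group
    curve_cols = config.curve_measurements or MEASUREMENT_NAMES
    curve_rows = []
    for sex_code, sex_name in ((1, "M"), (2, "F")):
        sub = normal[normal["sex"] == sex_code]
        for col in curve_cols:
            pts = sub.dropna(subset=["age_years", col])
            if len(pts) < 30:
                log.warning("stage=curves sex=%s measurement=%s skipped (n=%d < 30)",
                            sex_name, col, len(pts))
                continue
            cur = quantile_loess(
                pts["age_years"].to_numpy(), pts[col].to_numpy(), span=config.loess_span
            )
            cur.insert(0, "measurement", col)
            cur.insert(0, "sex", sex_name)
            curve_rows.append(cur)
    curves = (
        pd.concat(curve_rows, ignore_index=True)
        if curve_rows
        else pd.DataFrame(columns=["sex", "measurement", "grid", "q25", "q50", "q75"])
    )
    curves.to_csv(out / "curves.csv", index=False, float_format="%.10g")
    if config.make_plots and len(curves):
        _plot_curves(curves, out)

    manifest = {
        "software": {"name": "vesselmorph", "version": __version__},
        "config": config.as_dict(),
        "seed": config.seed,
        "plsr": chosen,
        "n_subjects": n_total,
        "input_hashes": hashes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _plot_curves(curves: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (sex, meas), sub in curves.groupby(["sex", "measurement"]):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for col, style in (("q25", "--"), ("q50", "-"), ("q75", "--")):
            ax.plot(sub["grid"], sub[col], style, label=col)
        ax.set_xlabel("age (years)")
        ax.set_ylabel(meas)
        ax.set_title(f"{meas} ({sex})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"curve_{meas}_{sex}.png", dpi=100)
        plt.close(fig)
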