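"""End-to-end orchestration: simulate -> derive -> onset -> dynamics -> sma -> sem.

Runs the whole heartwood analysis on a generated (or user-supplied)
two-cohort dataset and assembles report tables: a cohort trait summary
with Kruskal-Wallis contrasts, an SMA tapering grid, onset-threshold,
dynamics-selection and path-effect tables, plus a run manifest. The
pipeline is deterministic under a fixed (config, seed) pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import anatomy, datagen, dynamics, onset, pathmodel, sma

__all__ = ["RunConfig", "ReportBundle", "kruskal_wallis", "run_pipeline"]

logger = logging.getLogger("heartwoodkit")

RESULT_TABLES = (
    "trait_summary",
    "sma_results",
    "onset_results",
    "dynamics_results",
    "path_results",
    "path_contrasts",
)


def kruskal_wallis(
    groups, n_permutations: int = 0, random_state: int | None = 0
) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test across >= 2 samples.

    Returns (H, df, p) with the tie-corrected H statistic and the
    chi-square upper-tail p. With ``n_permutations > 0`` the p-value is
    instead estimated by permuting group labels (exact reference for
    small samples); the statistic itself is unchanged. Fully tied data
    give H = 0, p = 1.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    H, p = stats.kruskal(*groups)
    if n_permutations > 0:
        # rank-based H recomputed under label permutations; the tie
        # pattern (hence the correction factor) is permutation-invariant
        rng = np.random.default_rng(random_state)
        sizes = np.array([len(g) for g in groups])
        N = sizes.sum()
        ranks = stats.rankdata(pooled)
        _, counts = np.unique(pooled, return_counts=True)
        tie_corr = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
        edges = np.cumsum(sizes)[:-1]
        perms = np.array([rng.permutation(ranks) for _ in range(n_permutations)])
        h_perm = np.zeros(n_permutations)
        start = 0
        for size, end in zip(sizes, np.append(edges, N)):
            h_perm += perms[:, start:end].sum(axis=1) ** 2 / size
            start = end
        h_perm = (12.0 / (N * (N + 1)) * h_perm - 3 * (N + 1)) / tie_corr
        p = (np.sum(h_perm >= H - 1e-12) + 1) / (n_permutations + 1)
    return float(H), df, float(p)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int
    cohort_configs: dict | None = None  # name -> CohortConfig; None = defaults
    output_dir: str | Path | None = None
    alpha: float = 0.05
    gr_split: float = 0.55  # cm/yr, display split for onset thresholds
    stages: tuple[str, ...] = ("simulate", "derive", "onset", "dynamics", "sma", "sem")
    crossing: float = 0.0  # first-ring-age intercept convention
    p_adjust: str | None = None

    def manifest(self) -> dict:
        cfgs = self.cohort_configs or datagen.default_study_config()
        payload = {
            "seed": self.seed,
            "alpha": self.alpha,
            "gr_split": self.gr_split,
            "stages": list(self.stages),
            "crossing": self.crossing,
            "cohorts": {k: vars(v) if not isinstance(v, dict) else v for k, v in cfgs.items()},
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        payload["config_hash"] = digest
        return payload


@dataclass
class ReportBundle:
    """All result tables of one run, regenerable from the manifest."""

    manifest: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True, default=str),
            encoding="utf-8",
        )


_TRAIT_COLUMNS = {
    "GR": "GR",
    "D_H": "D_H",
    "N_V": "N_V",
    "A_V": "A_V",
    "TCVA": "TCVA",
    "F_V": "F_V",
}


def _trait_summary(derived: pd.DataFrame, dataset: dict, alpha: float) -> pd.DataFrame:
    """Cohort trait means +/- sd with pairwise Kruskal-Wallis letters."""
    cohorts = sorted(derived["cohort"].unique())
    rows = []

    def add(trait, per_cohort: dict):
        vals = {c: np.asarray(v, float) for c, v in per_cohort.items()}
        vals = {c: v[np.isfinite(v)] for c, v in vals.items()}
        if any(len(v) == 0 for v in vals.values()):
            return
        H, df, p = kruskal_wallis([vals[c] for c in cohorts])
        letters = (
            {c: "a" for c in cohorts}
            if p >= alpha
            else {c: l for c, l in zip(cohorts, "ab")}
        )
        for c in cohorts:
            rows.append(
                {
                    "trait": trait,
                    "cohort": c,
                    "mean": np.mean(vals[c]),
                    "sd": np.std(vals[c], ddof=1),
                    "n": len(vals[c]),
                    "kruskal_H": H,
                    "kruskal_p": p,
                    "letter": letters[c],
                }
            )

    trunk = derived[derived["disc_type"] == "trunk"]
    for trait, col in _TRAIT_COLUMNS.items():
        add(trait, {c: trunk.loc[trunk["cohort"] == c, col] for c in cohorts})

    # tree-level conduit tapering
    taper = {}
    for c in cohorts:
        vals = []
        for _, tree in trunk[trunk["cohort"] == c].groupby("tree_id"):
            f = sma.conduit_taper(tree["distance_from_top"], tree["D_H"])
            if f is not None:
                vals.append(f.slope)
        taper[c] = vals
    add("T_conduit", taper)

    leaves = dataset.get("leaves")
    if leaves is not None and len(leaves):
        lv = leaves.merge(
            dataset["trees"][["tree_id", "cohort"]], on="tree_id", how="left"
        )
        add("a_L", {c: lv.loc[lv["cohort"] == c, "mean_leaf_area_cm2"] for c in cohorts})
        add(
            "A_L_branch",
            {c: lv.loc[lv["cohort"] == c, "total_leaf_area_m2"] for c in cohorts},
        )
    stomata = dataset.get("stomata")
    if stomata is not None and len(stomata):
        st = stomata.merge(
            dataset["trees"][["tree_id", "cohort"]], on="tree_id", how="left"
        )
        g = [
            anatomy.gmax(d, s)
            for d, s in zip(st["stomatal_density_per_mm2"], st["stomatal_size_um2"])
        ]
        st = st.assign(gmax=g)
        add("G_max", {c: st.loc[st["cohort"] == c, "gmax"] for c in cohorts})
    return pd.DataFrame(rows)


def _onset_stage(derived: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Fit the four occurrence models and tabulate thresholds."""
    d = derived.assign(diameter=2 * derived["S_R"])
    rows = []
    fits: dict[str, onset.LogisticFit] = {}
    for spec in onset.PREDICTOR_SPECS:
        fit = onset.fit_occurrence(d, spec)
        fits[spec] = fit
        base = {
            "model": spec,
            "a": fit.a,
            "b": fit.b,
            "c": fit.c if fit.c is not None else np.nan,
            "se_a": fit.se()[0],
            "se_b": fit.se()[1],
            "se_c": fit.se()[2] if fit.c is not None else np.nan,
            "loglik": fit.loglik,
            "n": fit.n,
            "converged": fit.converged,
        }
        if not fit.converged:
            rows.append(base)
            continue
        if fit.c is None:
            evals = {"pooled": None}
        elif spec == "logD+site":
            evals = {"shaded": 0.0, "sun_exposed": 1.0}
        else:
            gr = d["GR"].to_numpy(float)
            slow = np.median(gr[gr < cfg.gr_split])
            fast = np.median(gr[gr >= cfg.gr_split])
            evals = {
                f"GR<{cfg.gr_split}": float(np.log(slow)),
                f"GR>={cfg.gr_split}": float(np.log(fast)),
            }
        for label, z in evals.items():
            th = onset.onset_threshold(fit, z, alpha=cfg.alpha)
            rows.append(
                {
                    **base,
                    "evaluated_at": label,
                    "threshold": th.point,
                    "ci_low": th.ci_low,
                    "ci_high": th.ci_high,
                    "scale": th.scale,
                }
            )
    # covariate LRTs against the nested single-predictor models
    lrt_d = onset.covariate_lrt(fits["logD+site"], fits["logD"])
    lrt_a = onset.covariate_lrt(fits["logAge+logGR"], fits["logAge"])
    for row in rows:
        if row["model"] == "logD+site":
            row["lrt_chi2"], row["lrt_df"], row["lrt_p"] = lrt_d
        elif row["model"] == "logAge+logGR":
            row["lrt_chi2"], row["lrt_df"], row["lrt_p"] = lrt_a
    return pd.DataFrame(rows)


def _dynamics_stage(derived: pd.DataFrame, cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Model selection + group LRTs for the heartwood responses vs age/diameter."""
    trunk = derived[(derived["disc_type"] == "trunk") & derived["hw_present"]]
    rows, extras = [], {}
    responses = {
        "hwa": trunk["HWa"].to_numpy(float),
        "hw_prop": trunk["hw_proportion"].to_numpy(float),
        "hw_rings": trunk["hw_rings"].to_numpy(float),
    }
    predictors = {
        "age": trunk["cambial_age"].to_numpy(float),
        "diameter": 2 * trunk["S_R"].to_numpy(float),
    }
    groups = trunk["cohort"].to_numpy()
    for rname, yv in responses.items():
        for pname, xv in predictors.items():
            fits = []
            for family in dynamics.FAMILIES:
                try:
                    fits.append(dynamics.fit_family(family, xv, yv))
                except (ValueError, RuntimeError):
                    continue
            sel = dynamics.select_model(fits)
            for f in fits:
                rows.append(
                    {
                        "response": rname,
                        "predictor": pname,
                        "family": f.family,
                        "params": json.dumps([round(v, 6) for v in f.params]),
                        "rse": f.rse,
                        "n": f.n,
                        "chosen": f.family == sel.chosen,
                    }
                )
            shared, per_group = dynamics.fit_family(sel.chosen, xv, yv, groups=groups)
            chi2, dfree, p = dynamics.group_lrt(shared, per_group)
            extras[(rname, pname)] = {
                "chosen": sel.chosen,
                "group_fits": per_group,
                "lrt": (chi2, dfree, p),
            }
            for row in rows:
                if (
                    row["response"] == rname
                    and row["predictor"] == pname
                    and row["chosen"]
                ):
                    row["group_lrt_chi2"], row["group_lrt_df"], row["group_lrt_p"] = (
                        chi2,
                        dfree,
                        p,
                    )
    # ring-conversion rates and first-ring ages from per-cohort linear fits
    ring_rows = []
    for cohort, grp in trunk.groupby("cohort"):
        fit = dynamics.fit_family(
            "linear", grp["cambial_age"].to_numpy(float), grp["hw_rings"].to_numpy(float)
        )
        age0, ci = dynamics.first_ring_age(fit, crossing=cfg.crossing, alpha=cfg.alpha)
        ring_rows.append(
            {
                "cohort": cohort,
                "ring_rate": fit.params[1],
                "ring_rate_se": fit.param_ses[1],
                "first_ring_age": age0,
                "first_ring_ci_low": ci[0],
                "first_ring_ci_high": ci[1],
            }
        )
    extras["ring_conversion"] = pd.DataFrame(ring_rows)
    return pd.DataFrame(rows), extras


_SMA_GRID = (
    ("S_R", "S_R"),
    ("SW_R", "SW_R"),
    ("HW_R", "HW_R"),
    ("CSa", "CSa"),
    ("SWa", "SWa"),
    ("HWa", "HWa"),
    ("D_H", "D_H"),
    ("TCVA", "TCVA"),
)


def _sma_stage(derived: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Tapering grid: per-cohort SMA of each variable against distance from top."""
    trunk = derived[derived["disc_type"] == "trunk"]
    rows = []
    for var, col in _SMA_GRID:
        per_cohort = {}
        for cohort, grp in trunk.groupby("cohort"):
            x = grp["distance_from_top"].to_numpy(float)
            y = grp[col].to_numpy(float)
            keep = np.isfinite(x) & np.isfinite(y) & (x >= 0.5) & (y > 0)
            if keep.sum() < 3:
                continue
            f = sma.sma_fit(x[keep], y[keep], x_label="L", y_label=var)
            per_cohort[cohort] = (x[keep], y[keep], f)
        if len(per_cohort) == 2:
            test = sma.common_slope_test(
                [(v[0], v[1]) for v in per_cohort.values()], log_transform=True
            )
            letters = dict(
                zip(sorted(per_cohort), "ab" if test.p < cfg.alpha else "aa")
            )
        else:
            test, letters = None, {c: "a" for c in per_cohort}
        for cohort, (_, _, f) in sorted(per_cohort.items()):
            rows.append(
                {
                    "variable": var,
                    "cohort": cohort,
                    "intercept": f.intercept,
                    "slope": f.slope,
                    "slope_ci_low": f.slope_ci[0],
                    "slope_ci_high": f.slope_ci[1],
                    "r2": f.r2,
                    "n": f.n,
                    "common_slope_p": test.p if test else np.nan,
                    "letter": letters[cohort],
                }
            )
    return pd.DataFrame(rows)


def _sem_stage(derived: pd.DataFrame, cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Path models per level and cohort, with indirect-vs-direct contrasts."""
    path_rows, contrast_rows = [], []
    for level in ("trunk", "branch"):
        sub = derived[derived["disc_type"] == level].copy()
        sub["D"] = 2 * sub["S_R"]
        sub["Age"] = sub["cambial_age"]
        if level == "trunk":
            spec = pathmodel.PathSpec(mediator="D", outcome="HWa", exogenous=("Age", "TCVA"))
            sub = sub.rename(columns={"TCVA": "TCVA"})
        else:
            spec = pathmodel.PathSpec(mediator="D", outcome="SWa", exogenous=("Age", "A_L"))
            sub = sub.rename(columns={"total_leaf_area_m2": "A_L"})
        for cohort, grp in sub.groupby("cohort"):
            cols = [spec.exogenous[0], spec.exogenous[1], spec.mediator, spec.outcome]
            try:
                model = pathmodel.fit_path(grp[cols], spec)
            except ValueError as exc:
                logger.warning("sem: skipping %s/%s (%s)", level, cohort, exc)
                continue
            eff = model.effects.assign(level=level, cohort=cohort)
            path_rows.append(eff)
            for pair in (
                (("age", "indirect"), ("hyd", "indirect")),
                (("hyd", "direct"), ("hyd", "indirect")),
                (("hyd", "total"), ("age", "indirect")),
            ):
                w = pathmodel.wald_contrast(model, *pair)
                contrast_rows.append(
                    {
                        "level": level,
                        "cohort": cohort,
                        "contrast": w.description,
                        "chi2": w.statistic,
                        "df": w.df,
                        "p": w.p,
                    }
                )
    path_results = (
        pd.concat(path_rows, ignore_index=True) if path_rows else pd.DataFrame()
    )
    return path_results, pd.DataFrame(contrast_rows)


def run_pipeline(config: RunConfig, dataset: dict | None = None) -> ReportBundle:
    """Execute the enabled stages in order and return the report bundle.

    ``dataset`` may supply pre-loaded tables (the frozen CSV schemas);
    otherwise the simulate stage generates them from the cohort configs
    and seed. Any stage failure aborts with the stage name and cause.
    """
    manifest = config.manifest()
    bundle = ReportBundle(manifest=manifest)
    stage = "init"
    try:
        if "simulate" in config.stages and dataset is None:
            stage = "simulate"
            dataset, truth = datagen.generate_study(config.cohort_configs, config.seed)
            bundle.extras["truth"] = truth
            logger.info(
                "[%s] simulate: %d trees, %d discs",
                manifest["config_hash"],
                len(dataset["trees"]),
                len(dataset["discs"]),
            )
        if dataset is None:
            raise ValueError("no dataset: enable the simulate stage or pass one")

        stage = "derive"
        derived = anatomy.derive_discs(
            dataset["discs"], dataset.get("vessels"), dataset.get("leaves")
        )
        bundle.extras["derived"] = derived
        logger.info("[%s] derive: %d rows", manifest["config_hash"], len(derived))

        stage = "report"
        bundle.tables["trait_summary"] = _trait_summary(derived, dataset, config.alpha)

        if "onset" in config.stages:
            stage = "onset"
            bundle.tables["onset_results"] = _onset_stage(derived, config)
        if "dynamics" in config.stages:
            stage = "dynamics"
            dyn_table, dyn_extras = _dynamics_stage(derived, config)
            bundle.tables["dynamics_results"] = dyn_table
            bundle.extras["dynamics"] = dyn_extras
            bundle.tables["ring_conversion"] = dyn_extras["ring_conversion"]
        if "sma" in config.stages:
            stage = "sma"
            bundle.tables["sma_results"] = _sma_stage(derived, config)
        if "sem" in config.stages:
            stage = "sem"
            path_results, contrasts = _sem_stage(derived, config)
            bundle.tables["path_results"] = path_results
            bundle.tables["path_contrasts"] = contrasts
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if config.output_dir is not None:
        bundle.write(config.output_dir)
    return bundle
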