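"""End-to-end orchestration: measurement, validation, comparative analyses.

Stage order mirrors the analysis flow: PCA, pairwise permutation tests,
phylogenetic-signal tests, allometric regressions with AIC ranking and
residual flags, MCMC ancestral states, fossil Z-scores.  Stage failures are
isolated: later independent stages still run, and the summary records every
failure.  Fossils never enter the tree or the regressions as data points;
they are evaluated only through expected-value predictions and Z-scores.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import allometry as allo
from . import bm_models, descriptive, morphometry, treeio
from .ancestral import ChainConfig, mcmc_ancestral, zscore_fossil
from .config import RunConfig
from .errors import CochlevolError, InvalidInputError

logger = logging.getLogger(__name__)

TRAITS = ("ECL", "TUR", "CUR", "RECL", "OWA")

#: units stamped into output column headers
UNITS = {"ECL": "mm", "TUR": "turns", "CUR": "ratio", "RECL": "mm",
         "OWA": "mm2", "body_mass_kg": "kg"}


def _write_tsv(df: pd.DataFrame, path: str, config: RunConfig, units: Optional[dict] = None):
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config.config_hash}\n")
        fh.write(f"# seed: {config.seed}\n")
        if units:
            parts = [f"{c}={u}" for c, u in units.items() if c in df.columns]
            if parts:
                fh.write("# units: " + ", ".join(parts) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def validate_inputs(config: RunConfig) -> list[str]:
    """Preflight checks; returns a list of problems (empty = clean)."""
    problems: list[str] = []
    tree = None
    if config.tree:
        try:
            tree = treeio.read_newick(config.tree)
        except CochlevolError as exc:
            problems.append(f"tree: {exc}")
    table = None
    if config.species_table:
        try:
            table = pd.read_csv(config.species_table)
        except Exception as exc:
            problems.append(f"species table: {exc}")
    if table is not None:
        if "species" not in table.columns:
            problems.append("species table: missing 'species' column")
        elif tree is not None:
            tips = set(treeio.tip_labels(tree))
            missing = sorted(set(table["species"].astype(str)) - tips)
            for sp in missing:
                problems.append(f"species {sp!r} absent from tree")
        if config.run_allometry and "body_mass_kg" not in table.columns:
            problems.append(
                "allometry enabled but species table lacks 'body_mass_kg'"
            )
        for col in TRAITS + ("body_mass_kg",):
            if col in table.columns:
                vals = pd.to_numeric(table[col], errors="coerce")
                if (vals <= 0).any():
                    problems.append(f"species table: nonpositive {col} values")
    if config.landmark_manifest:
        try:
            man = pd.read_csv(config.landmark_manifest)
            for col in ("specimen_id", "species", "spiral"):
                if col not in man.columns:
                    problems.append(f"landmark manifest: missing column {col!r}")
        except Exception as exc:
            problems.append(f"landmark manifest: {exc}")
    return problems


def run_measure(config: RunConfig) -> pd.DataFrame:
    """Measure every specimen listed in the landmark manifest.

    The manifest is a CSV with columns ``specimen_id, species, spiral,
    window, start`` (paths relative to the manifest; ``window`` optional per
    row).  Per-file failures are logged and summarized, not fatal.  Writes a
    rounded table, a full-precision twin, and a species summary with means
    and combined-sex CVs.
    """
    if not config.landmark_manifest:
        raise InvalidInputError("no landmark manifest configured")
    man = pd.read_csv(config.landmark_manifest)
    base = os.path.dirname(os.path.abspath(config.landmark_manifest))
    rows, rows_full, failures = [], [], []
    for rec in man.itertuples(index=False):
        try:
            spiral = morphometry.read_landmark_csv(
                os.path.join(base, rec.spiral), role="spiral",
                start=getattr(rec, "start", "base") or "base",
            )
            outline = None
            window = getattr(rec, "window", None)
            if isinstance(window, str) and window:
                outline = morphometry.read_landmark_csv(
                    os.path.join(base, window), role="window-outline")
            m = morphometry.measure_cochlea(spiral, outline)
        except (CochlevolError, OSError, ValueError) as exc:
            failures.append({"specimen_id": rec.specimen_id, "error": str(exc)})
            logger.error("measurement failed for %s: %s", rec.specimen_id, exc)
            continue
        common = {"specimen_id": rec.specimen_id, "species": rec.species}
        rows.append({**common, **m.rounded()})
        rows_full.append({**common, "ECL": m.ecl, "TUR": m.tur, "CUR": m.cur,
                          "RECL": m.recl, "OWA": m.owa})
    table = pd.DataFrame(rows, columns=["specimen_id", "species", *TRAITS])
    full = pd.DataFrame(rows_full, columns=["specimen_id", "species", *TRAITS])
    out = config.output_dir
    _write_tsv(table, os.path.join(out, "measurements.tsv"), config, UNITS)
    _write_tsv(full, os.path.join(out, "measurements_full.tsv"), config, UNITS)
    if failures:
        _write_tsv(pd.DataFrame(failures),
                   os.path.join(out, "measurement_failures.tsv"), config)
    if not full.empty:
        summary_rows = []
        for sp, grp in full.groupby("species", sort=True):
            row = {"species": sp, "n": len(grp)}
            for t in TRAITS:
                vals = grp[t].dropna().to_numpy(float)
                row[f"{t}_mean"] = vals.mean() if vals.size else np.nan
                row[f"{t}_cv"] = (
                    round(descriptive.coefficient_of_variation(vals), 2)
                    if vals.size >= 2 and vals.mean() != 0 else np.nan
                )
            summary_rows.append(row)
        _write_tsv(pd.DataFrame(summary_rows),
                   os.path.join(out, "species_summary.tsv"), config)
    return full


def _species_trait_frame(config: RunConfig):
    table = pd.read_csv(config.species_table)
    tree = treeio.read_newick(config.tree)
    pruned, ordered = treeio.align_table_to_tree(table, tree)
    return pruned, ordered


def run_comparative(config: RunConfig, specimen_table: Optional[pd.DataFrame] = None) -> dict:
    """Run the comparative stages; returns a status dict per stage."""
    status: dict[str, str] = {}
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    pruned, ordered = _species_trait_frame(config)
    V = treeio.vcv_from_tree(pruned)
    traits_present = [t for t in TRAITS if t in ordered.columns
                      and ordered[t].notna().all()]

    fossils = None
    if config.fossil_table:
        fossils = pd.read_csv(config.fossil_table)

    # --- PCA -------------------------------------------------------------
    if config.run_pca:
        try:
            cols = traits_present
            if len(cols) < 2:
                raise InvalidInputError("need >= 2 complete trait columns for PCA")
            res = descriptive.pca(ordered[cols].to_numpy(float),
                                  scale_mode=config.pca_scale_mode,
                                  variable_names=cols)
            df = pd.DataFrame({
                "component": [f"PC{i + 1}" for i in range(len(cols))],
                "percent_variance": res.percent_variance,
            })
            for i, name in enumerate(cols):
                df[f"corr_{name}"] = res.factor_map[i]
            _write_tsv(df, os.path.join(out, "pca.tsv"), config)
            status["pca"] = "ok"
        except Exception as exc:
            status["pca"] = f"failed: {exc}"
            logger.exception("PCA stage failed")

    # --- pairwise permutation tests -------------------------------------
    if config.run_permutation:
        try:
            if specimen_table is None or specimen_table.empty:
                status["permutation"] = "skipped: no specimen-level data"
            else:
                sub = specimen_table.dropna(subset=["RECL"])
                species = sorted(sub["species"].unique())
                mat = pd.DataFrame(index=species, columns=species, dtype=object)
                for i, s1 in enumerate(species):
                    for j, s2 in enumerate(species):
                        if i >= j:
                            continue
                        g1 = sub.loc[sub.species == s1, "RECL"].to_numpy(float)
                        g2 = sub.loc[sub.species == s2, "RECL"].to_numpy(float)
                        if g1.size < 2 or g2.size < 2:
                            mat.loc[s1, s2] = mat.loc[s2, s1] = ""
                            continue
                        res = descriptive.permutation_ttest(
                            g1, g2, n_perm=config.n_permutations,
                            seed=int(rng.integers(2**31)),
                        )
                        star = "*" if res.p <= config.alpha_level else ""
                        mat.loc[s1, s2] = f"{res.p:.5f}{star}"
                        mat.loc[s2, s1] = f"{res.p:.5f}{star}"
                mat.insert(0, "species", species)
                _write_tsv(mat, os.path.join(out, "permutation_matrix.tsv"), config)
                status["permutation"] = "ok"
        except Exception as exc:
            status["permutation"] = f"failed: {exc}"
            logger.exception("permutation stage failed")

    # --- phylogenetic signal --------------------------------------------
    if config.run_signal:
        try:
            rows = []
            cols = traits_present + (["body_mass_kg"]
                                     if "body_mass_kg" in ordered.columns else [])
            for trait in cols:
                y = ordered[trait].to_numpy(float)
                if config.signal_log_scale:
                    y = np.log10(y)
                res = bm_models.lambda_signal_test(y, V)
                rows.append({
                    "trait": trait,
                    "lambda_ml": res.lambda_ml,
                    "loglik_ml": res.loglik_ml,
                    "loglik_lambda0": res.loglik_lambda0,
                    "loglik_lambda1": res.loglik_lambda1,
                    "p_vs_0": res.p_vs_0,
                    "p_vs_1": res.p_vs_1,
                    "degenerate": res.degenerate,
                })
            _write_tsv(pd.DataFrame(rows), os.path.join(out, "signal.tsv"), config)
            status["signal"] = "ok"
        except Exception as exc:
            status["signal"] = f"failed: {exc}"
            logger.exception("signal stage failed")

    # --- allometry -------------------------------------------------------
    if config.run_allometry:
        try:
            if "body_mass_kg" not in ordered.columns:
                raise InvalidInputError("species table lacks 'body_mass_kg'")
            lx = np.log10(ordered["body_mass_kg"].to_numpy(float))
            fit_rows, resid_rows, pred_rows = [], [], []
            lam_mode = (config.lambda_mode if config.lambda_mode == "ml"
                        else float(config.lambda_mode))
            best_fits = {}
            for trait in traits_present:
                ly = np.log10(ordered[trait].to_numpy(float))
                fits = [
                    allo.ols_fit(ly, lx, response=trait, predictors=("body_mass",)),
                    allo.rma_fit(ly, lx, response=trait, predictors=("body_mass",)),
                    allo.pgls_fit(ly, lx, V, lam_mode=lam_mode, response=trait,
                                  predictors=("body_mass",)),
                ]
                ranked = allo.model_select_aic(fits)
                best_fits[trait] = next(f for f in fits if f.method == "PGLS")
                for rank, f in enumerate(ranked, start=1):
                    fit_rows.append({
                        "response": trait, "predictors": "+".join(f.predictors),
                        "method": f.method, "rank_aic": rank,
                        "intercept": f.intercept, "slope": f.slope,
                        "lambda": f.lam, "r_squared": f.r_squared,
                        "loglik": f.loglik, "aic": f.aic,
                    })
                z, flagged = allo.standardized_residuals(best_fits[trait])
                for sp, zi, fl in zip(ordered["species"], z, flagged):
                    resid_rows.append({"response": trait, "species": sp,
                                       "std_residual": zi, "flagged": bool(fl)})
            if fossils is not None and "body_mass_kg" in fossils.columns:
                for rec in fossils.itertuples(index=False):
                    trait = rec.trait
                    if trait in best_fits and np.isfinite(rec.body_mass_kg):
                        exp = allo.predict_expected(best_fits[trait],
                                                    float(rec.body_mass_kg))
                        pred_rows.append({
                            "fossil": rec.fossil, "trait": trait,
                            "observed": rec.value,
                            "expected_pgls": exp,
                            "body_mass_kg": rec.body_mass_kg,
                        })
            _write_tsv(pd.DataFrame(fit_rows),
                       os.path.join(out, "allometry.tsv"), config)
            _write_tsv(pd.DataFrame(resid_rows),
                       os.path.join(out, "allometry_residuals.tsv"), config)
            if pred_rows:
                _write_tsv(pd.DataFrame(pred_rows),
                           os.path.join(out, "fossil_expectations.tsv"), config)
            status["allometry"] = "ok"
        except Exception as exc:
            status["allometry"] = f"failed: {exc}"
            logger.exception("allometry stage failed")

    # --- ancestral states + fossil z-scores ------------------------------
    if config.run_ancestral:
        try:
            node_rows, z_rows = [], []
            chain = ChainConfig(iterations=config.mcmc_iterations,
                                burn_in=config.mcmc_burn_in,
                                thinning=config.mcmc_thinning,
                                seed=config.seed)
            posteriors_by_trait = {}
            for trait in traits_present:
                y = ordered[trait].to_numpy(float)
                post = mcmc_ancestral(y, pruned, chain, tip_order=V.tip_order)
                posteriors_by_trait[trait] = post
                for nid, p in post.items():
                    if nid.startswith("_"):
                        continue
                    node_rows.append({
                        "trait": trait, "node": nid,
                        "posterior_mean": p.mean, "posterior_sd": p.sd,
                        "q025": p.quantile(0.025), "q975": p.quantile(0.975),
                    })
            if fossils is not None:
                for rec in fossils.itertuples(index=False):
                    post = posteriors_by_trait.get(rec.trait)
                    if post is None:
                        continue
                    for nid, p in post.items():
                        if nid.startswith("_"):
                            continue
                        dev = zscore_fossil(float(rec.value), p, tail="auto",
                                            fossil=rec.fossil, trait=rec.trait,
                                            alpha_level=config.alpha_level)
                        z_rows.append({
                            "fossil": dev.fossil, "trait": dev.trait,
                            "node": dev.node_id, "z": dev.z, "p": dev.p,
                            "tail": dev.tail,
                            "significant": "*" if dev.significant else "",
                        })
            _write_tsv(pd.DataFrame(node_rows),
                       os.path.join(out, "ancestral_nodes.tsv"), config)
            if z_rows:
                _write_tsv(pd.DataFrame(z_rows),
                           os.path.join(out, "fossil_zscores.tsv"), config)
            status["ancestral"] = "ok"
        except Exception as exc:
            status["ancestral"] = f"failed: {exc}"
            logger.exception("ancestral stage failed")

    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump({"config": config.to_dict(),
                   "config_hash": config.config_hash,
                   "stages": status}, fh, indent=2, default=str)
    return status
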