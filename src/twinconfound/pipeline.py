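"""End-to-end pipeline: simulate -> preprocess -> twin fits -> GPS -> Gsens.

Driven by a plain dict (usually loaded from YAML); every stage writes
machine-readable JSON/CSV into the output directory and a run log records
the seed, package versions and stage timings.  All floating-point output is
rounded to 4 decimals so repeated runs with the same seed diff cleanly.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gsens import GsensInput, scenario_analysis, scenario_table
from .polygenic import ScoreMatrix, multiple_gps_regression
from .preprocess import intraclass_correlation, residualize, vdw_transform
from .simulate import (
    GpsSimConfig,
    TwinSimConfig,
    simulate_gps_cohort,
    simulate_univariate_twins,
    write_pairs_csv,
)
from .univariate import CorrelationSummary, fit_ace_ml_summary, profile_ci

log = logging.getLogger("twinconfound")


def _round(obj, nd: int = 4):
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), nd)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_round(obj), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the enabled stages in order; returns the summary bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info(
        "twinconfound %s | python %s | numpy %s | seed %d",
        __version__, sys.version.split()[0], np.__version__, seed,
    )

    bundle: dict = {"seed": seed}
    try:
        traits = config.get("traits", [])
        table_rows = []
        for i, tcfg in enumerate(traits):
            t0 = time.perf_counter()
            name = tcfg["name"]
            cfg = TwinSimConfig(
                n_mz=int(tcfg.get("n_mz", 2890)),
                n_dz=int(tcfg.get("n_dz", 4879)),
                a2=float(tcfg["a2"]),
                c2=float(tcfg["c2"]),
                e2=float(tcfg["e2"]),
                beta_age=float(tcfg.get("beta_age", 0.0)),
                beta_sex=float(tcfg.get("beta_sex", 0.0)),
                seed=seed + i,
                trait_names=(name,),
            )
            pairs = simulate_univariate_twins(cfg)
            write_pairs_csv(pairs, outdir / f"pairs_{name}.csv")

            # age/sex residualisation + rank-based normalisation, per twin slot
            for slot in ("1", "2"):
                col = f"{name}_{slot}"
                resid = residualize(pairs[col], pairs["age"], pairs[f"sex{slot}"])
                pairs[col] = vdw_transform(resid)

            icc_mz = intraclass_correlation(pairs, name, "MZ")
            icc_dz = intraclass_correlation(pairs, name, "DZ")
            fit = fit_ace_ml_summary(
                CorrelationSummary(icc_mz.r, icc_dz.r, icc_mz.n, icc_dz.n),
                seed=seed,
            )
            profile_ci(fit)
            row = {
                "trait": name,
                "A": fit.a2, "A_lo": fit.ci["a2"][0], "A_hi": fit.ci["a2"][1],
                "C": fit.c2, "C_lo": fit.ci["c2"][0], "C_hi": fit.ci["c2"][1],
                "E": fit.e2, "E_lo": fit.ci["e2"][0], "E_hi": fit.ci["e2"][1],
                "rMZ": icc_mz.r, "rMZ_lo": icc_mz.ci_low, "rMZ_hi": icc_mz.ci_high,
                "rDZ": icc_dz.r, "rDZ_lo": icc_dz.ci_low, "rDZ_hi": icc_dz.ci_high,
                "n_mz": icc_mz.n, "n_dz": icc_dz.n,
            }
            table_rows.append(row)
            log.info("univariate %s done in %.2fs", name, time.perf_counter() - t0)
        if table_rows:
            table = pd.DataFrame(table_rows).set_index("trait").round(4)
            table.to_csv(outdir / "ace_table.csv", float_format="%.4f")
            bundle["ace_table"] = table.reset_index().to_dict(orient="records")
            _write_json(outdir / "univariate.json", bundle["ace_table"])

        if "gps" in config:
            t0 = time.perf_counter()
            g = config["gps"]
            cohort = simulate_gps_cohort(
                GpsSimConfig(
                    n=int(g.get("n", 6000)),
                    h2_y=float(g.get("h2_y", 0.4)),
                    r2_gps=float(g.get("r2_gps", 0.01)),
                    b_gx=float(g.get("b_gx", 0.3)),
                    b_xy=float(g.get("b_xy", 0.0)),
                    seed=seed + 100,
                )
            )
            k = int(g.get("n_scores", 9))
            rng = np.random.default_rng(seed + 101)
            scores = pd.DataFrame(
                {"gps_target": cohort["GPS"]}
                | {f"gps_null_{j}": rng.standard_normal(len(cohort)) for j in range(1, k)}
            )
            assoc = multiple_gps_regression(ScoreMatrix(scores), cohort["Y"])
            bundle["gps"] = {
                "multiple_R": assoc.multiple_R,
                "R2": assoc.R2,
                "adj_R2": assoc.adj_R2,
                "f_pvalue": assoc.f_pvalue,
                "n": assoc.n,
                "per_score": assoc.per_score.round(4).reset_index().to_dict("records"),
            }
            _write_json(outdir / "gps.json", bundle["gps"])
            assoc.per_score.round(4).to_csv(outdir / "gps_per_score.csv")
            log.info("gps stage done in %.2fs", time.perf_counter() - t0)

        if "gsens" in config:
            t0 = time.perf_counter()
            s = config["gsens"]
            inp = GsensInput(
                r_gx=float(s["r_gx"]),
                r_gy=float(s["r_gy"]),
                r_xy=float(s["r_xy"]),
                n=int(s.get("n", 6000)),
                h2_snp=float(s["h2_snp"]),
                h2_twin=float(s["h2_twin"]),
            )
            results = scenario_analysis(
                inp,
                bootstrap=bool(s.get("bootstrap", False)),
                n_boot=int(s.get("n_boot", 1000)),
                seed=seed + 200,
            )
            tab = scenario_table(results).round(4)
            tab.to_csv(outdir / "gsens_scenarios.csv", float_format="%.4f")
            bundle["gsens"] = tab.reset_index().to_dict(orient="records")
            _write_json(outdir / "gsens.json", bundle["gsens"])
            log.info("gsens stage done in %.2fs", time.perf_counter() - t0)

        _write_json(outdir / "summary.json", bundle)
    except Exception:
        log.exception("pipeline halted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return bundle


def load_config(path: str | Path) -> dict:
    import yaml

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text())
    for key in ("input", "scores"):
        ref = cfg.get(key)
        if ref and not Path(ref).exists():
            raise FileNotFoundError(f"config references missing file: {ref}")
    return cfg
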