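"""File I/O and the ``evrtest`` command line.

Data files are plain CSV with header columns ``x, y, z``: x and y numeric,
z either category labels (categorical analysis) or numbers (continuous
analysis).  Missing values are an error, never silently dropped.

Subcommands:

* ``test``     — EVR analysis of a dataset (moments, slopes in both
  directions, theta Wald tests with exp(theta) CIs, and the LR ladder for
  categorical moderators; ML fit with theta_1 and dr1 Wald tests for
  continuous moderators);
* ``simulate`` — run a named design cell or a scenario file through the
  Monte-Carlo harness;
* ``fixture``  — emit a seeded draw from the two-condition example
  population (rho = 0.45 in both conditions, sd_y 2 vs 1, sd_x 1).

Results go to stdout (or ``--output``) as JSON or text; logging goes to
stderr.  Every report embeds the seed, package version and resolved
configuration.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .categorical import moderation_report
from .continuous import deltar1_test, fit_continuous, theta1_test
from .model_core import BivariateSample, TestConfig, all_group_moments
from .samplers import build_scenario, sample_scenario, scenario_from_file
from .simulation import run_simulation

__all__ = ["read_dataset", "write_dataset", "cli_main", "main"]

log = logging.getLogger("evrtest")


def read_dataset(path, kind: str) -> BivariateSample:
    """Read a CSV with columns x, y, z into a typed sample.

    Raises on missing columns, non-numeric x/y, empty files, and missing
    values (the offending row is named).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; need header x,y,z")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: missing or non-numeric value in column {col!r} at data row {row}"
            )
        df[col] = vals
    if df["z"].isna().any():
        row = int(np.flatnonzero(df["z"].isna())[0])
        raise ValueError(f"{path}: missing value in column 'z' at data row {row}")
    if kind == "continuous":
        z = pd.to_numeric(df["z"], errors="coerce")
        if z.isna().any():
            row = int(np.flatnonzero(z.isna())[0])
            raise ValueError(
                f"{path}: non-numeric moderator at data row {row} (continuous mode)"
            )
        moderator = z.to_numpy(float)
    else:
        moderator = df["z"].astype(str).to_numpy(dtype=object)
    return BivariateSample(
        df["x"].to_numpy(float), df["y"].to_numpy(float), moderator, kind=kind
    )


def write_dataset(sample: BivariateSample, path) -> None:
    pd.DataFrame(
        {"x": sample.x, "y": sample.y, "z": sample.moderator}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def _render_text(report: dict) -> str:
    lines = []
    push = lines.append
    push(f"evrtest {report['meta']['version']} — EVR moderation analysis")
    push(f"seed: {report['meta']['seed']}  config: {report['meta']['config']}")
    push("")
    if "groups" in report:
        push("Group moments (ML, divisor n):")
        for g in report["groups"]:
            push(
                f"  {g['label']}: n={g['n']}  sd_x={g['sd_x']:.4f} "
                f"sd_y={g['sd_y']:.4f}  r={g['r']:.4f}  "
                f"b(y|x)={g['slope_y_on_x']:.4f}  b(x|y)={g['slope_x_on_y']:.4f}"
            )
        push("")
        push("EVR theta tests (target vs base):")
        for t in report["theta_tests"]:
            push(
                f"  [{t['test_category']}] vs [{t['base_category']}]: "
                f"theta={t['theta_hat']:.4f}  se={t['se']:.4f}  z={t['statistic']:.3f} "
                f"p={t['p_value']:.4g}  exp(theta) CI=({t['ci_exp_theta'][0]:.3f}, "
                f"{t['ci_exp_theta'][1]:.3f})"
            )
        push("")
        push("Correlation (Fisher-link) tests:")
        for t in report["correlation_tests"]:
            push(
                f"  {t['label']}: est={t['estimate']:.4f} z={t['statistic']:.3f} "
                f"p={t['p_value']:.4g}"
            )
        push("")
        lad = report["lr_ladder"]
        push(f"LR ladder (baseline: {lad['baseline']}):")
        for s in lad["steps"]:
            push(
                f"  + {sorted(set(s['constraints_restricted']) - set(s['constraints_full']))}:"
                f" chi2({s['df']}) = {s['chi2']:.3f}, p = {s['p_value']:.4g}"
            )
    else:
        push("Continuous-moderator ML fit:")
        push(f"  coefficients: {report['coefficients']}")
        t = report["theta1_test"]
        push(
            f"  theta1 = {t['theta_hat']:.4f} (se {t['se']:.4f}), z = "
            f"{t['statistic']:.3f}, p = {t['p_value']:.4g}"
        )
        d = report["delta_r1_test"]
        push(
            f"  dr1    = {d['estimate']:.4f} (se {d['se']:.4f}), z = "
            f"{d['statistic']:.3f}, p = {d['p_value']:.4g}"
        )
    return "\n".join(lines) + "\n"


def _emit(payload: dict, fmt: str, output) -> None:
    if fmt == "json":
        text = json.dumps(payload, indent=2, default=float) + "\n"
    else:
        text = _render_text(payload)
    if output:
        Path(output).write_text(text)
    else:
        sys.stdout.write(text)


def _meta(args, config: TestConfig) -> dict:
    return {
        "version": __version__,
        "seed": getattr(args, "seed", None),
        "config": {
            "alpha": config.alpha,
            "critical_value_family": config.critical_value_family,
        },
    }


# ---------------------------------------------------------------------------
# subcommands
# ---------------------------------------------------------------------------


def _cmd_test(args) -> int:
    config = TestConfig(alpha=args.alpha, critical_value_family=args.family)
    sample = read_dataset(args.input, args.moderator)
    if args.moderator == "categorical":
        groups = all_group_moments(sample)
        base = args.base if args.base is not None else groups[0].label
        report = moderation_report(groups, config, base=base)
    else:
        fit = fit_continuous(sample)
        report = {
            "coefficients": {
                "gamma_x": fit.params.gamma_x.tolist(),
                "gamma_y": fit.params.gamma_y.tolist(),
                "delta_x": fit.params.delta_x.tolist(),
                "delta_y": fit.params.delta_y.tolist(),
                "delta_r": fit.params.delta_r.tolist(),
            },
            "loglik": fit.loglik,
            "theta1_test": theta1_test(fit, config).to_dict(),
            "delta_r1_test": deltar1_test(fit, config).to_dict(),
        }
    report["meta"] = _meta(args, config)
    _emit(report, args.format, args.output)
    return 0


def _cmd_simulate(args) -> int:
    config = TestConfig(alpha=args.alpha, critical_value_family=args.family)
    if args.scenario:
        spec = scenario_from_file(args.scenario)
    else:
        if args.table is None:
            raise ValueError("provide --table or --scenario")
        sizes = tuple(args.sizes) if args.sizes else None
        spec = build_scenario(args.table, args.condition, sizes=sizes, skew=args.skew)
    tests = tuple(args.tests.split(",")) if args.tests else None
    log.info("scenario %s, reps=%d, seed=%d", spec.name, args.reps, args.seed)
    res = run_simulation(spec, args.reps, config, tests=tests, seed=args.seed)
    payload = res.to_dict()
    payload["meta"] = _meta(args, config)
    if args.format == "text":
        sys.stdout.write(json.dumps(payload, indent=2, default=float) + "\n")
    else:
        _emit(payload, "json", args.output)
    return 0


def _cmd_fixture(args) -> int:
    spec = build_scenario("sem_example", sizes=(args.n,))
    sample = sample_scenario(spec, seed=args.seed)
    out = args.output or "-"
    if out == "-":
        write_dataset(sample, sys.stdout)
    else:
        write_dataset(sample, out)
    log.info(
        "wrote %d rows of the two-condition example population (seed %d)",
        sample.n, args.seed,
    )
    return 0


def _build_parser() -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(
        prog="evrtest",
        description="Equal-variance-ratio tests: are slopes and correlations "
        "equivalently moderated?",
    )
    ap.add_argument("--version", action="version", version=f"evrtest {__version__}")
    sub = ap.add_subparsers(dest="command", required=True)

    t = sub.add_parser("test", help="EVR analysis of a CSV dataset")
    t.add_argument("--input", required=True)
    t.add_argument("--moderator", choices=("categorical", "continuous"),
                   default="categorical")
    t.add_argument("--base", default=None, help="base category (categorical)")
    t.add_argument("--alpha", type=float, default=0.05)
    t.add_argument("--family", choices=("normal", "t"), default="normal")
    t.add_argument("--format", choices=("json", "text"), default="json")
    t.add_argument("--output", default=None)
    t.set_defaults(func=_cmd_test, seed=None)

    s = sub.add_parser("simulate", help="Monte-Carlo run of a design cell")
    s.add_argument("--table", default=None, help='design id ("1".."7", "sem_example")')
    s.add_argument("--condition", type=int, default=1)
    s.add_argument("--sizes", type=int, nargs="+", default=None)
    s.add_argument("--skew", type=float, default=None)
    s.add_argument("--scenario", default=None, help="YAML/JSON scenario file")
    s.add_argument("--reps", type=int, default=20000)
    s.add_argument("--seed", type=int, default=0)
    s.add_argument("--tests", default=None,
                   help="comma-separated subset, e.g. theta,delta_r")
    s.add_argument("--alpha", type=float, default=0.05)
    s.add_argument("--family", choices=("normal", "t"), default="normal")
    s.add_argument("--format", choices=("json", "text"), default="json")
    s.add_argument("--output", default=None)
    s.set_defaults(func=_cmd_simulate)

    f = sub.add_parser("fixture", help="emit the two-condition example dataset")
    f.add_argument("--seed", type=int, default=0)
    f.add_argument("--n", type=int, default=300, help="per-condition sample size")
    f.add_argument("--output", default=None)
    f.set_defaults(func=_cmd_fixture)
    return ap


def cli_main(argv=None) -> int:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s: %(message)s")
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)
    try:
        return args.func(args)
    except (ValueError, KeyError, OSError) as exc:
        log.error("%s", exc)
        return 1


def main() -> None:
    sys.exit(cli_main())
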