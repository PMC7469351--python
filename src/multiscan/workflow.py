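"""Command-line orchestration: scan, select-test and simulate subcommands.

Thin wrappers over the library.  Every run writes a manifest (config echo,
seed, package version) next to its outputs so it can be reproduced
bit-identically.  Results go to files; structured logs to stderr.  Exit
codes: 0 ok, 1 invalid input, 2 runtime failure.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .inference import overall_test
from .scan import CandidateSequence, ScanConfig, scp_candidates
from .selection import SelectionResult, select
from .simulate import SCENARIO_RRS, make_scenario, power_study
from .spatial import (
    CaseData,
    RegionMap,
    derive_adjacency,
    drop_zero_expected,
    load_cases,
    load_regions,
    read_adjacency,
)

logger = logging.getLogger("multiscan")


def _fail(code: int, message: str) -> None:
    logger.error(message)
    sys.exit(code)


def _load_inputs(coords, cases, expected, population, adjacency, knn,
                 geographic):
    for label, path in (("coordinates", coords), ("cases", cases),
                        ("expected", expected), ("population", population)):
        if path is not None and not Path(path).exists():
            _fail(1, f"{label} file not found: {path}")
    if adjacency is not None and not Path(adjacency).exists():
        _fail(1, f"adjacency file not found: {adjacency}")
    if expected is None and population is None:
        _fail(1, "either --expected or --population is required")
    try:
        rmap = load_regions(coords, geographic=geographic)
        if adjacency is not None:
            rmap = read_adjacency(adjacency, rmap)
        elif knn:
            rmap = derive_adjacency(rmap, knn)
        if expected is not None:
            data = load_cases(cases, rmap, expected_source=expected)
        else:
            # proportional (unstratified) indirect standardization
            from .spatial import _read_table, expected_counts

            cdf = _read_table(cases, 2)
            counts = np.zeros(rmap.m, dtype=np.int64)
            for row in range(cdf.shape[0]):
                counts[rmap.index_of(str(cdf.iloc[row, 0]).strip())] = \
                    int(float(cdf.iloc[row, 1]))
            pdf = _read_table(population, 2)
            pop = np.zeros(rmap.m)
            for row in range(pdf.shape[0]):
                pop[rmap.index_of(str(pdf.iloc[row, 0]).strip())] = \
                    float(pdf.iloc[row, 1])
            with np.errstate(all="ignore"):
                mu0 = expected_counts(pop, total_cases=int(counts.sum()))
            data = None
            rmap, data, _ = drop_zero_expected(rmap, counts, mu0)
            return rmap, data
    except (ValueError, KeyError) as exc:
        _fail(1, f"invalid input: {exc}")
    rmap, data, _ = drop_zero_expected(rmap, data.observed, data.expected0)
    return rmap, data


def _scan_config(method, max_fraction, neighbor_limit, alpha1, kmax,
                 ps_threshold, replications) -> ScanConfig:
    try:
        return ScanConfig(method=method, max_fraction=max_fraction,
                          neighbor_limit=neighbor_limit, alpha1=alpha1,
                          kmax=kmax, ps_threshold=ps_threshold,
                          replications=replications)
    except ValueError as exc:
        _fail(1, f"invalid scan configuration: {exc}")
        raise AssertionError  # unreachable


def _write_manifest(outdir: Path, command: str, params: dict) -> None:
    manifest = {"command": command, "version": __version__, **params}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _candidates_frame(cands: CandidateSequence, rmap: RegionMap,
                      data: CaseData) -> pd.DataFrame:
    o, e = data.total_observed, data.total_expected
    rows = []
    for rank, c in enumerate(cands, start=1):
        idx = sorted(c.window.members)
        out_rate = (o - c.observed_in) / (e - c.expected_in)
        rows.append({
            "rank": rank,
            "region_ids": ";".join(rmap.region_ids[i] for i in idx),
            "n_regions": c.window.size,
            "observed": c.observed_in,
            "expected": c.expected_in,
            "RR": c.smr,                       # window SMR O_w / E_w
            "RR_vs_outside": c.smr / out_rate,  # theta_w / theta_outside
            "llr": c.llr,
            "p_s": c.p_s,
        })
    return pd.DataFrame(rows)


_input_options = [
    click.option("--coords", required=True, help="coordinates file (id x y)"),
    click.option("--cases", required=True, help="case file (id count)"),
    click.option("--expected", default=None,
                 help="baseline expected-count file (id expected)"),
    click.option("--population", default=None,
                 help="population file (id population); proportional "
                      "standardization when --expected is absent"),
    click.option("--adjacency", default=None,
                 help="adjacency matrix or edge-list file"),
    click.option("--knn", default=0, type=int,
                 help="derive adjacency as mutualized k-NN if no file given"),
    click.option("--geographic", is_flag=True,
                 help="centroids are (lat, lon) in degrees"),
]

_scan_options = [
    click.option("--method", default="circular",
                 type=click.Choice(["circular", "flexible", "restricted"])),
    click.option("--max-fraction", default=0.5, type=float),
    click.option("--neighbor-limit", default=20, type=int),
    click.option("--alpha1", default=0.2, type=float),
    click.option("--kmax", default=20, type=int),
    click.option("--ps-threshold", default=1.0, type=float),
]


def _add_options(options):
    def deco(f):
        for opt in reversed(options):
            f = opt(f)
        return f
    return deco


@click.group()
@click.version_option(__version__)
def main() -> None:
    """Multiple spatial disease-cluster detection."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@main.command("scan")
@_add_options(_input_options)
@_add_options(_scan_options)
@click.option("--replications", default=999, type=int,
              help="Monte Carlo replications for per-cluster p_s (0 = skip)")
@click.option("--seed", default=0, type=int)
@click.option("--outdir", default="multiscan_out", type=click.Path())
def cmd_scan(coords, cases, expected, population, adjacency, knn, geographic,
             method, max_fraction, neighbor_limit, alpha1, kmax, ps_threshold,
             replications, seed, outdir) -> None:
    """Run the sequential scan and write the candidate-cluster table."""
    rmap, data = _load_inputs(coords, cases, expected, population, adjacency,
                              knn, geographic)
    cfg = _scan_config(method, max_fraction, neighbor_limit, alpha1, kmax,
                       ps_threshold, replications)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        cands = scp_candidates(data, rmap, cfg, rng=seed)
    except Exception as exc:  # pragma: no cover - defensive
        _fail(2, f"scan failed: {exc}")
        raise
    _candidates_frame(cands, rmap, data).to_csv(out / "candidates.csv", index=False)
    _write_manifest(out, "scan", {"seed": seed, "scan_config": asdict(cfg),
                                  "m": rmap.m, "total_observed": data.total_observed})
    click.echo(f"wrote {out / 'candidates.csv'} ({len(cands)} candidates)")


def _selection_outputs(out: Path, sel: SelectionResult, rmap: RegionMap) -> None:
    kmax = len(sel.c_trace)
    trace = pd.DataFrame({
        "K": np.arange(1, kmax + 1),
        "loglik": sel.loglik_trace,
        "minus2logL": sel.minus2loglik_trace,
        "AIC": sel.aic_trace,
        "BIC": sel.bic_trace,
        "C": sel.c_trace,
        "RDC": sel.rdc_trace,
    })
    trace.to_csv(out / "criterion_trace.csv", index=False)
    summary = {
        "C0": sel.c0,
        "k_hat": sel.k_hat,
        "max_RDC": sel.max_rdc,
        "p_M": sel.p_m,
        "selected_clusters": [
            sorted(rmap.region_ids[i] for i in w.members)
            for w in sel.selected_windows
        ],
    }
    (out / "selection.json").write_text(json.dumps(summary, indent=2))


@main.command("select-test")
@_add_options(_input_options)
@_add_options(_scan_options)
@click.option("--replications", default=999, type=int,
              help="Monte Carlo replications R for the overall test")
@click.option("--no-test", is_flag=True, help="skip the overall Monte Carlo test")
@click.option("--fixed-windows", is_flag=True,
              help="refit observed windows on null replicates instead of rescanning")
@click.option("--seed", default=0, type=int)
@click.option("--outdir", default="multiscan_out", type=click.Path())
def cmd_select_test(coords, cases, expected, population, adjacency, knn,
                    geographic, method, max_fraction, neighbor_limit, alpha1,
                    kmax, ps_threshold, replications, no_test, fixed_windows,
                    seed, outdir) -> None:
    """Select the number of clusters by max RDC(K) and test the model."""
    rmap, data = _load_inputs(coords, cases, expected, population, adjacency,
                              knn, geographic)
    cfg = _scan_config(method, max_fraction, neighbor_limit, alpha1, kmax,
                       ps_threshold, 0)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        if no_test:
            cands = scp_candidates(data, rmap, cfg)
            sel = select(cands, data, rmap.m)
        else:
            sel = overall_test(data, rmap, cfg, R=replications, seed=seed,
                               regenerate=not fixed_windows)
    except Exception as exc:  # pragma: no cover - defensive
        _fail(2, f"selection failed: {exc}")
        raise
    _selection_outputs(out, sel, rmap)
    _write_manifest(out, "select-test", {
        "seed": seed, "scan_config": asdict(cfg), "R": replications,
        "no_test": no_test, "fixed_windows": fixed_windows, "m": rmap.m,
    })
    click.echo(f"K_hat = {sel.k_hat}, max RDC = {sel.max_rdc:.4f}, "
               f"p_M = {sel.p_m if sel.p_m is not None else 'not tested'}")


@main.command("simulate")
@click.option("--scenario", "tag", default="S1")
@click.option("--n-datasets", default=100, type=int)
@click.option("--n-regions", default=324, type=int)
@click.option("--layout", default="lattice",
              type=click.Choice(["lattice", "random-planar"]))
@click.option("--sizes", default="5,7,8,8,5",
              help="comma-separated cluster sizes")
@click.option("--method", default="proposed", type=click.Choice(["proposed", "scp"]))
@click.option("--level", default=0.05, type=float)
@click.option("--replications", default=99, type=int)
@click.option("--kmax", default=8, type=int)
@click.option("--seed", default=0, type=int)
@click.option("--outdir", default="multiscan_out", type=click.Path())
def cmd_simulate(tag, n_datasets, n_regions, layout, sizes, method, level,
                 replications, kmax, seed, outdir) -> None:
    """Run a planted-cluster simulation scenario and summarize power/Sen/PPV."""
    if tag not in SCENARIO_RRS:
        _fail(1, f"unknown scenario {tag!r}; valid tags: "
                 f"{', '.join(sorted(SCENARIO_RRS))}")
    try:
        size_tuple = tuple(int(s) for s in sizes.split(","))
    except ValueError:
        _fail(1, f"invalid --sizes: {sizes!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        scenario = make_scenario(tag, n_regions=n_regions, layout=layout,
                                 sizes=size_tuple, seed=seed)
        cfg = ScanConfig(kmax=kmax, replications=0)
        summary, table = power_study(scenario, n_datasets=n_datasets, level=level,
                                     R=replications, method=method,
                                     scan_config=cfg, seed=seed)
    except Exception as exc:  # pragma: no cover - defensive
        _fail(2, f"simulation failed: {exc}")
        raise
    table.to_csv(out / f"{tag}_{method}_datasets.csv", index=False)
    (out / f"{tag}_{method}_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    _write_manifest(out, "simulate", {
        "seed": seed, "scenario": tag, "n_datasets": n_datasets,
        "method": method, "level": level, "R": replications, "kmax": kmax,
    })
    click.echo(json.dumps(summary, indent=2, default=float))


if __name__ == "__main__":  # pragma: no cover
    main()
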