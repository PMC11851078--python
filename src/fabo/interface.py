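"""Command-line entry points: ``fabo simulate``, ``fabo run``, ``fabo report``.

The CLI never computes anything itself — it parses, dispatches to the
library, and serializes, so every number in a report is reproducible
through the API.  A run directory contains one JSON-lines trace per trial,
a ``manifest.json`` (effective config, master seed, per-trial seeds, input
digests, version, timestamps) and a ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from datetime import datetime, timezone
from pathlib import Path

import click
import yaml

from . import __version__
from .campaign import CampaignConfig, CampaignTrace, run_benchmark, spawn_trial_seeds
from .data_model import load_oracle, load_pool, save_groups, save_oracle, save_pool
from .evaluation import aggregate, plot_search_efficiency
from .feature_selection import load_fixed_features
from .synthetic import make_pool, paper_shape_preset, save_ground_truth, save_task_spec

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config_file(path: str | None) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise click.UsageError(f"config file {path} must hold a mapping")
    return data


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Per-cycle log lines to stderr.")
def main(verbose: bool) -> None:
    """Feature-adaptive Bayesian optimization over candidate pools."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command()
@click.option("--preset", type=click.Choice(["high_pressure_like", "low_pressure_like", "band_gap_like"]), default="high_pressure_like", show_default=True)
@click.option("--n-candidates", type=int, default=2000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(file_okay=False), required=True)
def simulate(preset: str, n_candidates: int, seed: int, out: str) -> None:
    """Write a synthetic pool (features, labels, groups, ground truth)."""
    spec = paper_shape_preset(preset, n_candidates=n_candidates, seed=seed)
    pool, oracle, truth = make_pool(spec)
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_pool(pool, out_dir / "features.csv")
    save_oracle(oracle, out_dir / "labels.csv")
    save_groups(pool, out_dir / "groups.csv")
    save_ground_truth(truth, out_dir / "ground_truth.json")
    save_task_spec(spec, out_dir / "task_spec.json")
    click.echo(f"wrote synthetic task '{preset}' ({pool.n_candidates} candidates, "
               f"{pool.n_features} features) to {out_dir}")


@main.command()
@click.option("--features", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--labels", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--groups", type=click.Path(exists=True, dir_okay=False))
@click.option("--config", "config_path", type=click.Path(exists=True, dir_okay=False))
@click.option("--variant", type=click.Choice(["fabo", "random_search", "random_features", "fixed_features", "full_ard", "rf_surrogate"]))
@click.option("--direction", type=click.Choice(["maximize", "minimize"]), default="maximize", show_default=True)
@click.option("--budget", type=int)
@click.option("--trials", type=int)
@click.option("--seed", type=int)
@click.option("--fixed-features-file", type=click.Path(exists=True, dir_okay=False),
              help="One feature name per line; required for variant=fixed_features.")
@click.option("--jobs", type=int, default=1, show_default=True)
@click.option("--out", type=click.Path(file_okay=False), required=True)
def run(features, labels, groups, config_path, variant, direction, budget,
        trials, seed, fixed_features_file, jobs, out) -> None:
    """Run a multi-trial screening benchmark; flags override config values."""
    cfg_dict = _load_config_file(config_path)
    if variant is not None:
        cfg_dict["variant"] = variant
    if budget is not None:
        cfg_dict["budget"] = budget
    if trials is not None:
        cfg_dict["n_trials"] = trials
    if seed is not None:
        cfg_dict["master_seed"] = seed
    try:
        config = CampaignConfig.from_dict(cfg_dict)
        pool = load_pool(features, groups_path=groups)
        oracle = load_oracle(labels, direction=direction, pool=pool)
        fixed_idx = None
        if config.variant == "fixed_features":
            if fixed_features_file is None:
                raise ValueError("variant=fixed_features needs --fixed-features-file")
            fixed_idx = load_fixed_features(fixed_features_file, pool.feature_names)
    except (ValueError, FileNotFoundError) as exc:
        raise click.UsageError(str(exc))

    started = datetime.now(timezone.utc).isoformat()
    try:
        traces = run_benchmark(pool, oracle, config, fixed_idx, n_jobs=jobs)
    except RuntimeError as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)

    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(traces):
        t.to_jsonl(out_dir / f"trial_{i:03d}.jsonl")
    summary = aggregate(traces, oracle, pool_ids=pool.ids)
    summary.save(out_dir / "summary.json")
    manifest = {
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "trial_seeds": spawn_trial_seeds(config.master_seed, config.n_trials),
        "inputs": {
            "features": _sha256(Path(features)),
            "labels": _sha256(Path(labels)),
            "groups": _sha256(Path(groups)) if groups else None,
        },
        "direction": direction,
        "version": __version__,
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    click.echo(f"wrote {len(traces)} traces, summary and manifest to {out_dir}")


def _load_run_dir(run_dir: Path) -> tuple[list[CampaignTrace], dict]:
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise click.UsageError(f"{run_dir} is not a run directory (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    trace_files = sorted(run_dir.glob("trial_*.jsonl"))
    if not trace_files:
        raise click.UsageError(f"no trace files in {run_dir}")
    traces = []
    for p in trace_files:
        try:
            traces.append(CampaignTrace.from_jsonl(p))
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            raise click.ClickException(f"malformed trace file {p}: {exc}")
    return traces, manifest


@main.command()
@click.option("--run", "run_dirs", type=click.Path(exists=True, file_okay=False),
              multiple=True, required=True,
              help="Run directory; repeat for side-by-side comparison.")
@click.option("--labels", type=click.Path(exists=True, dir_okay=False), required=True)
@click.option("--top-k", type=int, default=100, show_default=True)
@click.option("--out", type=click.Path(file_okay=False), required=True)
def report(run_dirs, labels, top_k, out) -> None:
    """Summarize run directories: metrics JSON + search-efficiency plots."""
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for rd in run_dirs:
        rd = Path(rd)
        traces, manifest = _load_run_dir(rd)
        direction = manifest.get("direction", "maximize")
        oracle = load_oracle(labels, direction=direction)
        summary = aggregate(traces, oracle, top_k=top_k)
        summaries[rd.name] = summary
        summary.save(out_dir / f"summary_{rd.name}.json")
    plot_search_efficiency(summaries, out_dir)
    click.echo(f"wrote {len(summaries)} summaries and plots to {out_dir}")


if __name__ == "__main__":
    main()
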