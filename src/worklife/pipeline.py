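"""End-to-end pipeline orchestration and the ``worklife`` command line.

Stages: simulate -> measures/cohort filter -> transition-rate costs ->
OM distances -> Ward clustering with stopping-rule diagnostics -> outcome
models -> margins.  Every stage is a pure function of (inputs, config,
seed); ``run_all`` writes the full artifact set plus a manifest of content
hashes so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import measures, models, sequences, synth

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Pipeline configuration; echoed verbatim into the run manifest."""

    seed: int = 0
    n: int = 1000
    out_dir: str = "worklife_run"
    sleep_formula: str = "mean2"  # mean2 | weighted52
    cost_model: str = "trate"  # trate | const:2 | const:3 ...
    indel: float = 1.0
    ward_variant: str = "d2"  # d2 | d
    k: int | None = None
    k_max: int = 10
    outcomes: tuple = tuple(models.DEFAULT_MODEL_SPECS)
    interactions: tuple = ("female", "race", "education")
    missing_rates: dict = field(default_factory=dict)
    biennial: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["outcomes"] = list(self.outcomes)
        data["interactions"] = list(self.interactions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def make_cost_model(panel: sequences.SequencePanel, config: RunConfig):
    if config.cost_model == "trate":
        tm = sequences.estimate_transition_rates(panel)
        return sequences.trate_costs(tm, indel=config.indel)
    if config.cost_model.startswith("const:"):
        value = float(config.cost_model.split(":", 1)[1])
        return sequences.constant_costs(value, indel=config.indel)
    raise ValueError(
        f"unknown cost model {config.cost_model!r}; use 'trate' or 'const:<value>'"
    )


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format=FLOAT_FMT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run every stage and write the artifact directory.

    Produces, in order: sequence CSVs (long + wide), covariates/outcomes
    CSVs, cost-matrix echo, condensed distance matrix, linkage/labels/
    diagnostics, state-distribution table, per-outcome model tables,
    margins tables, and ``manifest.json`` with seed and content hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)
        click.echo(msg)

    # -- stage 1: simulate ------------------------------------------------
    bundle = synth.generate_bundle(config.n, config.seed)
    if config.missing_rates or config.biennial:
        bundle = synth.inject_missingness(
            bundle, config.missing_rates, biennial=config.biennial
        )
    say(f"simulated panel: n={bundle.n}, seed={config.seed}")
    _write_csv(bundle.sequences.to_long(), out / "sequences_long.csv")
    _write_csv(bundle.sequences.to_wide(), out / "sequences_wide.csv")
    _write_csv(
        bundle.covariates.rename_axis("person_id"), out / "covariates.csv", index=True
    )
    _write_csv(
        bundle.outcomes.rename_axis("person_id"), out / "outcomes.csv", index=True
    )
    if bundle.truth is not None:
        _write_csv(
            bundle.truth.rename_axis("person_id").to_frame(),
            out / "truth_labels.csv",
            index=True,
        )

    # -- stage 2: cohort filter -------------------------------------------
    target = config.outcomes[0] if config.outcomes else "sleep_hours"
    cohort, exclusions = measures.cohort_filter(bundle, outcome=target)
    _write_csv(exclusions.to_frame(), out / "exclusion_log.csv")
    say(f"cohort filter on {target!r}: retained {exclusions.retained}/{bundle.n}")

    # -- stage 3: costs + distances ----------------------------------------
    panel = cohort.sequences.fill_gaps()
    cm = make_cost_model(panel, config)
    _write_csv(cm.to_frame().rename_axis("state"), out / "cost_matrix.csv", index=True)
    mem = sequences.estimate_pairwise_memory(panel.n)
    say(f"distance matrix: {panel.n} sequences, {mem / 1e6:.1f} MB condensed")
    dm = sequences.pairwise_distances(panel, cm)
    dm.save(out / "distances.npz")

    # -- stage 4: cluster ---------------------------------------------------
    tree = cl.ward_linkage(dm, variant=config.ward_variant)
    sol = cl.cluster_solution(
        tree, dm, k=config.k, k_range=range(2, config.k_max + 1)
    )
    say(f"clustering: k={sol.k} ({sol.rationale})")
    _write_csv(
        pd.DataFrame(
            tree.merges, columns=["child_a", "child_b", "height", "size"]
        ),
        out / "linkage.csv",
    )
    labels = pd.DataFrame({"person_id": panel.ids, "cluster": sol.labels})
    _write_csv(labels, out / "cluster_labels.csv")
    _write_csv(sol.diagnostics, out / "cluster_diagnostics.csv")
    _write_csv(cl.state_distribution(panel, sol.labels), out / "state_distribution.csv")

    # -- stage 5: models + margins -----------------------------------------
    named = _name_clusters(panel, sol.labels)
    collected_warnings: list[str] = []
    fitted_outcomes = []
    for outcome in config.outcomes:
        spec = models.default_model_spec(outcome)
        try:
            fit = models.fit_outcome(cohort.covariates, named, cohort.outcomes, spec)
        except (ValueError, RuntimeError) as err:
            # separation / rank problems are data conditions at small n:
            # recorded in the manifest, remaining outcomes still run
            collected_warnings.append(f"model {outcome}: {err}")
            say(f"model {outcome}: skipped ({err})")
            continue
        fitted_outcomes.append(outcome)
        _write_csv(fit.summary_frame(), out / f"model_{outcome}.csv")
        ok = (~cohort.outcomes[outcome].isna()).to_numpy()
        margins = models.adjusted_predictions(
            fit, cohort.covariates.loc[ok], named[ok], focal=spec.pattern_col
        )
        _write_csv(margins.table, out / f"margins_{outcome}.csv")
        say(f"model {outcome}: n={fit.n}, fit={fit.fit_stat:.3f}")
    if config.interactions and fitted_outcomes:
        try:
            suite = models.interaction_suite(
                cohort.covariates,
                named,
                cohort.outcomes,
                outcome_names=fitted_outcomes,
                markers=tuple(config.interactions),
            )
            _write_csv(suite, out / "margins_interactions.csv")
            say("interaction margins written")
        except (ValueError, RuntimeError) as err:
            collected_warnings.append(f"interaction margins: {err}")
            say(f"interaction margins: skipped ({err})")

    # -- manifest -----------------------------------------------------------
    config.to_yaml(out / "config.yaml")
    files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "n": config.n,
        "python": sys.version.split()[0],
        "config": asdict(config),
        "log": log,
        "warnings": collected_warnings,
        "hashes": {p.name: _sha256(p) for p in files},
    }
    manifest["config"]["outcomes"] = list(config.outcomes)
    manifest["config"]["interactions"] = list(config.interactions)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    say(f"artifacts in {out}")
    return out


def _name_clusters(panel: sequences.SequencePanel, labels: np.ndarray) -> np.ndarray:
    """Map numeric cluster ids to descriptive pattern names.

    The cluster whose members spend the most person-years in standard hours
    is the stable-ST reference; remaining clusters keep generic names.  With
    the default synthetic archetypes this puts the reference where the
    regression contrasts expect it.
    """
    ids = np.unique(labels)
    st = list(panel.alphabet).index("ST")
    st_share = {
        c: (panel.codes[labels == c] == st).mean() for c in ids
    }
    ref = max(st_share, key=st_share.get)
    named = np.empty(len(labels), dtype=object)
    for c in ids:
        named[labels == c] = "stable_st" if c == ref else f"pattern_{c}"
    return named


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------


def _load_config(config_path, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    return cfg


@click.group()
def cli() -> None:
    """Work-schedule life-course sequence analysis pipeline."""


_seed = click.option("--seed", type=int, default=None, help="master random seed")
_config = click.option("--config", "config_path", type=click.Path(exists=True), default=None)
_out = click.option("--out", "out_dir", type=click.Path(), default=None)


@cli.command()
@_seed
@_config
@_out
@click.option("--n", type=int, default=None, help="panel size")
def simulate(seed, config_path, out_dir, n):
    """Generate a synthetic panel (sequences, covariates, outcomes)."""
    cfg = _load_config(config_path, seed=seed, out_dir=out_dir, n=n)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = synth.generate_bundle(cfg.n, cfg.seed)
    _write_csv(bundle.sequences.to_long(), out / "sequences_long.csv")
    _write_csv(bundle.sequences.to_wide(), out / "sequences_wide.csv")
    _write_csv(bundle.covariates.rename_axis("person_id"), out / "covariates.csv", index=True)
    _write_csv(bundle.outcomes.rename_axis("person_id"), out / "outcomes.csv", index=True)
    _write_csv(bundle.truth.rename_axis("person_id").to_frame(), out / "truth_labels.csv", index=True)
    click.echo(f"wrote panel n={cfg.n} to {out}")


@cli.command()
@click.option("--outcomes", "outcomes_csv", type=click.Path(exists=True), required=True)
@_out
@click.option("--sleep-formula", type=click.Choice(["mean2", "weighted52"]), default="mean2")
def measures_cmd(outcomes_csv, out_dir, sleep_formula):
    """Recompute derived scales from item-level outcome columns."""
    frame = pd.read_csv(outcomes_csv, index_col="person_id")
    out = Path(out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    derived = pd.DataFrame(index=frame.index)
    derived["sleep_hours"] = measures.weekly_sleep_average(
        frame["sleep_weekday"], frame["sleep_weekend"], formula=sleep_formula
    )
    quality, alpha = measures.sleep_quality_score(
        frame[[f"sleep_quality_item{j}" for j in range(1, 5)]]
    )
    derived["sleep_quality"] = quality
    derived["poor_health"] = measures.poor_health(frame["general_health"])
    cesd = measures.cesd_score_frame(frame[[f"cesd_item{j}" for j in range(1, 8)]])
    derived["cesd_score"] = cesd["cesd_score"]
    derived["cesd_risk"] = cesd["cesd_risk"]
    _write_csv(derived.rename_axis("person_id"), out / "derived_scales.csv", index=True)
    click.echo(f"sleep-quality Cronbach alpha: {alpha:.3f}")
    click.echo(f"wrote {out / 'derived_scales.csv'}")


cli.add_command(measures_cmd, name="measures")


@cli.command()
@click.option("--sequences", "seq_csv", type=click.Path(exists=True), required=True,
              help="long CSV (person_id, age, state)")
@_out
@click.option("--sub", "cost_model", default="trate", help="trate or const:<value>")
@click.option("--indel", type=float, default=1.0)
def distances(seq_csv, out_dir, cost_model, indel):
    """Transition-rate costs and pairwise OM distances."""
    panel = sequences.SequencePanel.from_long(pd.read_csv(seq_csv)).fill_gaps()
    cfg = RunConfig(cost_model=cost_model, indel=indel)
    cm = make_cost_model(panel, cfg)
    out = Path(out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(cm.to_frame().rename_axis("state"), out / "cost_matrix.csv", index=True)
    dm = sequences.pairwise_distances(panel, cm)
    dm.save(out / "distances.npz")
    _write_csv(dm.to_frame().rename_axis("person_id"), out / "distances_square.csv", index=True)
    click.echo(f"wrote {dm.n}x{dm.n} distance matrix to {out}")


@cli.command("cluster")
@click.option("--distances", "dist_file", type=click.Path(exists=True), required=True)
@click.option("--sequences", "seq_csv", type=click.Path(exists=True), default=None)
@_out
@click.option("--ward", "ward_variant", type=click.Choice(["d2", "d"]), default="d2")
@click.option("--k", type=int, default=None)
@click.option("--kmax", type=int, default=10)
def cluster_cmd(dist_file, seq_csv, out_dir, ward_variant, k, kmax):
    """Ward clustering with CH / Duda-Hart diagnostics."""
    dm = sequences.DistanceMatrix.load(dist_file)
    tree = cl.ward_linkage(dm, variant=ward_variant)
    sol = cl.cluster_solution(tree, dm, k=k, k_range=range(2, kmax + 1))
    out = Path(out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(pd.DataFrame({"person_id": dm.ids, "cluster": sol.labels}),
               out / "cluster_labels.csv")
    _write_csv(sol.diagnostics, out / "cluster_diagnostics.csv")
    if seq_csv:
        panel = sequences.SequencePanel.from_long(pd.read_csv(seq_csv)).fill_gaps()
        _write_csv(cl.state_distribution(panel, sol.labels), out / "state_distribution.csv")
    click.echo(sol.rationale)


@cli.command("model")
@click.option("--covariates", "cov_csv", type=click.Path(exists=True), required=True)
@click.option("--outcomes", "out_csv", type=click.Path(exists=True), required=True)
@click.option("--labels", "lab_csv", type=click.Path(exists=True), required=True)
@click.option("--outcome", required=True, type=click.Choice(list(models.DEFAULT_MODEL_SPECS)))
@click.option("--interaction", type=click.Choice(["none", "gender", "race", "education"]),
              default="none")
@_out
def model_cmd(cov_csv, out_csv, lab_csv, outcome, interaction, out_dir):
    """Fit one covariate-adjusted outcome model with robust SEs."""
    cov = pd.read_csv(cov_csv, index_col="person_id")
    outc = pd.read_csv(out_csv, index_col="person_id")
    lab = pd.read_csv(lab_csv, index_col="person_id").iloc[:, 0]
    marker = {"none": None, "gender": "female", "race": "race", "education": "education"}[interaction]
    spec = models.default_model_spec(outcome, interaction=marker)
    fit = models.fit_outcome(cov, lab.to_numpy(dtype=object), outc, spec)
    out = Path(out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(fit.summary_frame(), out / f"model_{outcome}.csv")
    click.echo(f"n={fit.n}, fit={fit.fit_stat:.4f}; wrote model_{outcome}.csv")


@cli.command("margins")
@click.option("--covariates", "cov_csv", type=click.Path(exists=True), required=True)
@click.option("--outcomes", "out_csv", type=click.Path(exists=True), required=True)
@click.option("--labels", "lab_csv", type=click.Path(exists=True), required=True)
@click.option("--outcome", required=True, type=click.Choice(list(models.DEFAULT_MODEL_SPECS)))
@_out
def margins_cmd(cov_csv, out_csv, lab_csv, outcome, out_dir):
    """Average adjusted predictions by employment pattern."""
    cov = pd.read_csv(cov_csv, index_col="person_id")
    outc = pd.read_csv(out_csv, index_col="person_id")
    lab = pd.read_csv(lab_csv, index_col="person_id").iloc[:, 0].to_numpy(dtype=object)
    spec = models.default_model_spec(outcome)
    fit = models.fit_outcome(cov, lab, outc, spec)
    ok = (~outc[outcome].isna()).to_numpy()
    res = models.adjusted_predictions(fit, cov.loc[ok], lab[ok], focal=spec.pattern_col)
    out = Path(out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(res.table, out / f"margins_{outcome}.csv")
    click.echo(res.table.to_string(index=False))


@cli.command("run-all")
@_seed
@_config
@_out
@click.option("--n", type=int, default=None)
@click.option("--k", type=int, default=None)
def run_all_cmd(seed, config_path, out_dir, n, k):
    """Run the full pipeline: simulate through margins."""
    cfg = _load_config(config_path, seed=seed, out_dir=out_dir, n=n, k=k)
    run_all(cfg)


if __name__ == "__main__":
    cli()
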