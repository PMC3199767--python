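"""Configuration, serialization and command-line entry point.

One canonical YAML config (versioned schema) carries the full prior table,
observation triplet, sampler settings, variant label, promoter-partition
convention and cell geometry.  Every run logs the seed, a config hash and
the partition convention -- the model's main structural ambiguity -- so any
output is regenerable from its sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import click
import pandas as pd
import yaml

from . import __version__
from .core_model import (
    CHAIN_STATIONARY,
    PARAM_NAMES,
    PARTITION_CONVENTIONS,
    CellGeometry,
    KineticParameters,
    simulate,
    steady_state,
    make_mutant,
)
from .bayes_inference import (
    DEFAULT_PROPOSAL_SCALES,
    Observations,
    PosteriorChain,
    Prior,
    default_priors,
    mh_run,
    summarize_posterior,
    tune_acceptance,
)
from .sensitivity_mca import coefficient_table
from .repression_variants import (
    REPRESSION_BENCHMARK,
    VARIANT_LABELS,
    crossing_copy_number,
    make_variant,
    ratio_curve,
    variant_pi,
)
from .synthetic_data import generate as generate_dataset, truth_preset

__all__ = ["ConfigError", "SamplerSettings", "RunConfig", "default_config",
           "load_config", "save_config", "load_parameters", "save_parameters",
           "save_chain", "cli", "main"]

SCHEMA_VERSION = 1

#: Units of each model parameter, as used in the prior table.
PARAM_UNITS = {
    "k_A": "s^-1", "k_B": "s^-1",
    "k1": "nM", "k2": "nM", "k3": "nM", "k4": "nM",
    "sigma_A": "s^-1", "sigma_B": "s^-1",
    "lambda_A": "nM^-1 s^-1", "lambda_B": "nM^-1 s^-1",
    "gamma_P": "s^-1",
    "pi_X": "-", "pi_Y": "-",
    "D0": "nM",
}

log = logging.getLogger("korab")


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the key."""


@dataclass(frozen=True)
class SamplerSettings:
    iterations: int = 100_000
    seed: int = 1
    rate_scale: float = DEFAULT_PROPOSAL_SCALES[0]
    pi_scale: float = DEFAULT_PROPOSAL_SCALES[1]
    burn_in: float = 0.1
    thinning: int = 360

    def __post_init__(self):
        if self.iterations < 1:
            raise ConfigError("sampler.iterations must be >= 1")
        if not (0 <= self.burn_in < 1):
            raise ConfigError("sampler.burn_in must lie in [0, 1)")
        if self.thinning < 1:
            raise ConfigError("sampler.thinning must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    priors: dict[str, Prior]
    observations: Observations = Observations()
    sampler: SamplerSettings = SamplerSettings()
    variant: str | None = None
    partition_convention: str = CHAIN_STATIONARY
    geometry: CellGeometry = CellGeometry()
    output_dir: str = "."
    verbosity: str = "info"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        missing = [n for n in PARAM_NAMES if n not in self.priors]
        if missing:
            raise ConfigError(f"priors missing for parameter(s): {missing}")
        unknown = [n for n in self.priors if n not in PARAM_NAMES]
        if unknown:
            raise ConfigError(f"unknown parameter(s) in priors: {unknown}")
        if self.partition_convention not in PARTITION_CONVENTIONS:
            raise ConfigError(
                f"partition_convention must be one of {PARTITION_CONVENTIONS}")
        if self.variant is not None and self.variant not in VARIANT_LABELS:
            raise ConfigError(f"variant must be one of {VARIANT_LABELS}")

    def to_dict(self) -> dict:
        priors = {}
        for name in PARAM_NAMES:
            pr = self.priors[name]
            entry = {"family": pr.family, "unit": PARAM_UNITS[name]}
            if pr.mode is not None:
                entry["mode"] = pr.mode
            if pr.cv is not None:
                entry["cv"] = pr.cv
            if pr.bounds is not None:
                entry["bounds"] = list(pr.bounds)
            priors[name] = entry
        return {
            "schema_version": self.schema_version,
            "partition_convention": self.partition_convention,
            "variant": self.variant,
            "verbosity": self.verbosity,
            "output_dir": self.output_dir,
            "geometry": {"volume": self.geometry.volume},
            "observations": asdict(self.observations),
            "sampler": asdict(self.sampler),
            "priors": priors,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


_TOP_KEYS = {"schema_version", "partition_convention", "variant", "verbosity",
             "output_dir", "geometry", "observations", "sampler", "priors"}
_PRIOR_KEYS = {"family", "mode", "cv", "bounds", "unit"}


def default_config(tight: bool = False) -> RunConfig:
    """The bundled defaults: measured prior table and observation triplet."""
    obs = Observations(cv=0.1 if tight else 0.5)
    return RunConfig(priors=default_priors(tight=tight), observations=obs)


def _prior_from_entry(name: str, entry: dict) -> Prior:
    if not isinstance(entry, dict):
        raise ConfigError(f"priors.{name} must be a mapping")
    unknown = set(entry) - _PRIOR_KEYS
    if unknown:
        raise ConfigError(f"priors.{name}: unknown key(s) {sorted(unknown)}")
    if "family" not in entry:
        raise ConfigError(f"priors.{name}: missing 'family'")
    unit = entry.get("unit")
    if unit is not None and unit != PARAM_UNITS[name]:
        raise ConfigError(
            f"priors.{name}: unit {unit!r} does not match expected "
            f"{PARAM_UNITS[name]!r}")
    cv = entry.get("cv")
    if cv is not None and cv <= 0:
        raise ConfigError(f"priors.{name}: cv must be > 0, got {cv}")
    bounds = entry.get("bounds")
    if bounds is not None:
        if (not isinstance(bounds, (list, tuple)) or len(bounds) != 2
                or not bounds[0] < bounds[1]):
            raise ConfigError(f"priors.{name}: malformed bounds {bounds!r}")
        bounds = (float(bounds[0]), float(bounds[1]))
    try:
        return Prior(entry["family"], mode=entry.get("mode"), cv=cv,
                     bounds=bounds)
    except ValueError as exc:
        raise ConfigError(f"priors.{name}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version "
                          f"{raw.get('schema_version')!r}")
    prior_entries = raw.get("priors")
    if not isinstance(prior_entries, dict):
        raise ConfigError("missing or malformed 'priors' table")
    priors = {name: _prior_from_entry(name, entry)
              for name, entry in prior_entries.items()
              if name in PARAM_NAMES}
    unknown_priors = [n for n in prior_entries if n not in PARAM_NAMES]
    if unknown_priors:
        raise ConfigError(f"unknown parameter(s) in priors: {unknown_priors}")
    try:
        obs = Observations(**raw.get("observations", {}))
        sampler = SamplerSettings(**raw.get("sampler", {}))
        geometry = CellGeometry(**raw.get("geometry", {}))
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(
        priors=priors, observations=obs, sampler=sampler,
        variant=raw.get("variant"),
        partition_convention=raw.get("partition_convention", CHAIN_STATIONARY),
        geometry=geometry, output_dir=raw.get("output_dir", "."),
        verbosity=raw.get("verbosity", "info"),
    )


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_parameters(path) -> KineticParameters:
    """Read a flat name -> value YAML map of kinetic parameters."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"parameter file {path} is not a mapping")
    unknown = set(raw) - set(PARAM_NAMES)
    if unknown:
        raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
    try:
        return KineticParameters(**{k: float(v) for k, v in raw.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_parameters(params: KineticParameters, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def save_chain(chain: PosteriorChain, out_dir, config: RunConfig | None = None,
               store_every: int = 1) -> tuple[Path, Path]:
    """Write a chain as delimited text plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "chain.csv"
    meta_path = out / "chain_meta.json"
    chain.to_dataframe().iloc[::store_every].to_csv(csv_path, index=False)
    meta = {
        "version": __version__,
        "seed": chain.seed,
        "proposal_scales": list(chain.scales),
        "iterations": len(chain),
        "store_every": store_every,
        "sampled": list(chain.sampled),
        "partition_convention": (config.partition_convention if config
                                 else CHAIN_STATIONARY),
        "config_hash": config.hash() if config else None,
        "priors": {n: {"family": p.family, "mode": p.mode, "cv": p.cv,
                       "bounds": list(p.bounds) if p.bounds else None}
                   for n, p in chain.priors.items()},
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return csv_path, meta_path


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------


def _setup_logging(verbosity: str = "info"):
    logging.basicConfig(
        level=getattr(logging, verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def _resolve_params(params_file, variant, mutant) -> KineticParameters:
    if params_file:
        p = load_parameters(params_file)
    elif variant:
        p = make_variant(variant)
    else:
        raise click.UsageError("provide --params FILE or --variant LABEL")
    return make_mutant(p) if mutant else p


@click.group(no_args_is_help=False)
@click.version_option(__version__)
def cli():
    """Model, fit and analyse the RK2 central control operon."""


@cli.command("simulate")
@click.option("--params", "params_file", type=click.Path(exists=True))
@click.option("--variant", type=click.Choice(VARIANT_LABELS))
@click.option("--t-end", type=float, default=6.0e4, show_default=True,
              help="Integration horizon in seconds.")
@click.option("--mutant", is_flag=True, help="Cooperativity knockout (k3=k1, k4=k2).")
@click.option("--convention", default=CHAIN_STATIONARY,
              type=click.Choice(PARTITION_CONVENTIONS), show_default=True)
@click.option("--out", type=click.Path(), required=True)
def cli_simulate(params_file, variant, t_end, mutant, convention, out):
    """Integrate the ODEs and write the trajectory as CSV."""
    _setup_logging()
    p = _resolve_params(params_file, variant, mutant)
    log.info("simulate: convention=%s t_end=%g", convention, t_end)
    traj = simulate(p, t_end=t_end, convention=convention)
    traj.to_csv(out, index=False)
    click.echo(f"trajectory ({len(traj)} points) written to {out}")


@cli.command("steady")
@click.option("--params", "params_file", type=click.Path(exists=True))
@click.option("--variant", type=click.Choice(VARIANT_LABELS))
@click.option("--mutant", is_flag=True)
@click.option("--convention", default=CHAIN_STATIONARY,
              type=click.Choice(PARTITION_CONVENTIONS), show_default=True)
@click.option("--out", type=click.Path(), default=None)
def cli_steady(params_file, variant, mutant, convention, out):
    """Solve for the steady state and print the totals."""
    _setup_logging()
    p = _resolve_params(params_file, variant, mutant)
    st, info = steady_state(p, convention=convention, return_info=True)
    if info["multiple"]:
        click.echo(f"warning: {info['n_roots']} distinct steady states; "
                   "reporting the one reached from the empty cell", err=True)
    for name in ("A1", "A2", "B1", "B2"):
        click.echo(f"{name} = {getattr(st, name):.6g} nM")
    click.echo(f"A_tot = {st.A_tot:.6g} nM")
    click.echo(f"B_tot = {st.B_tot:.6g} nM")
    if out:
        pd.DataFrame([{"A1": st.A1, "A2": st.A2, "B1": st.B1, "B2": st.B2,
                       "A_tot": st.A_tot, "B_tot": st.B_tot}]
                     ).to_csv(out, index=False)


@cli.command("fit")
@click.option("--config", "config_file", type=click.Path(exists=True))
@click.option("--iterations", type=int, default=None,
              help="Override sampler.iterations.")
@click.option("--seed", type=int, default=None, help="Override sampler.seed.")
@click.option("--variant", type=click.Choice(("full",) + VARIANT_LABELS),
              default="full", show_default=True)
@click.option("--store-every", type=int, default=10, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def cli_fit(config_file, iterations, seed, variant, store_every, out):
    """Run the blocked Metropolis-Hastings fit; write chain + summary."""
    cfg = load_config(config_file) if config_file else default_config(
        tight=(variant != "full"))
    _setup_logging(cfg.verbosity)
    priors = dict(cfg.priors)
    if variant != "full":
        cX, cY = variant_pi(variant)
        priors["sigma_A"] = Prior("point", mode=0.0)
        priors["sigma_B"] = Prior("point", mode=0.0)
        if cX is not None:
            priors["pi_X"] = Prior("point", mode=cX)
        if cY is not None:
            priors["pi_Y"] = Prior("point", mode=cY)
    n_iter = iterations or cfg.sampler.iterations
    run_seed = seed if seed is not None else cfg.sampler.seed
    log.info("fit: variant=%s iterations=%d seed=%d convention=%s config=%s",
             variant, n_iter, run_seed, cfg.partition_convention, cfg.hash())
    chain = mh_run(priors, cfg.observations, iterations=n_iter, seed=run_seed,
                   scales=(cfg.sampler.rate_scale, cfg.sampler.pi_scale),
                   convention=cfg.partition_convention)
    csv_path, meta_path = save_chain(chain, out, cfg, store_every=store_every)
    click.echo(f"chain written to {csv_path} (metadata {meta_path})")
    click.echo(tune_acceptance(chain).to_string())
    thinning = min(cfg.sampler.thinning,
                   max(1, int(0.9 * n_iter) // 200))
    summary = summarize_posterior(chain, burn_in=cfg.sampler.burn_in,
                                  thinning=thinning)
    summary.to_csv(Path(out) / "posterior_summary.csv")
    click.echo(summary.to_string())


@cli.command("mca")
@click.option("--params", "params_file", type=click.Path(exists=True))
@click.option("--variant", type=click.Choice(VARIANT_LABELS), default="uu",
              show_default=True)
@click.option("--convention", default=CHAIN_STATIONARY,
              type=click.Choice(PARTITION_CONVENTIONS), show_default=True)
@click.option("--out", type=click.Path(), required=True)
def cli_mca(params_file, variant, convention, out):
    """Concentration control coefficients at a parameter point."""
    _setup_logging()
    p = _resolve_params(params_file, variant, mutant=False)
    table = coefficient_table(p, convention=convention)
    long = table.to_long()
    long.to_csv(out, index=False)
    click.echo(long.to_string(index=False))


@cli.command("variants")
@click.option("--models", default="11,uu,u0,0u,00", show_default=True,
              help="Comma-separated variant labels.")
@click.option("--copies", default="1:60", show_default=True,
              help="Copy-number range lo:hi (inclusive).")
@click.option("--threshold", type=float, default=REPRESSION_BENCHMARK,
              show_default=True)
@click.option("--convention", default=CHAIN_STATIONARY,
              type=click.Choice(PARTITION_CONVENTIONS), show_default=True)
@click.option("--out", type=click.Path(), required=True)
def cli_variants(models, copies, threshold, convention, out):
    """Repression-ratio curves and threshold crossings per variant."""
    _setup_logging()
    try:
        lo, hi = (int(x) for x in copies.split(":"))
    except ValueError:
        raise click.UsageError(f"malformed --copies {copies!r}; expected lo:hi")
    frames = []
    for label in models.split(","):
        label = label.strip()
        curve = ratio_curve(label, copies=range(lo, hi + 1),
                            convention=convention)
        curve.insert(0, "model", label)
        cross = crossing_copy_number(curve, threshold)
        click.echo(f"model {label}: ratio first reaches {threshold} at "
                   f"copy number {cross if cross is not None else '(none in range)'}")
        frames.append(curve)
    pd.concat(frames, ignore_index=True).to_csv(out, index=False)
    click.echo(f"curves written to {out}")


@cli.command("generate")
@click.option("--truth", "truth_file", type=click.Path(exists=True),
              help="YAML parameter file of the ground truth.")
@click.option("--preset", type=click.Choice(("uu", "u0")), default="uu",
              show_default=True)
@click.option("--cv", type=float, default=0.5, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def cli_generate(truth_file, preset, cv, seed, out):
    """Generate a synthetic observation triplet from known ground truth."""
    _setup_logging()
    truth = (load_parameters(truth_file) if truth_file
             else truth_preset(preset))
    ds = generate_dataset(truth, cv=cv, seed=seed)
    payload = {
        "observations": asdict(ds.observations),
        "noiseless": {"A_tot_wt": ds.noiseless[0],
                      "B_tot_wt": ds.noiseless[1],
                      "B_tot_mut": ds.noiseless[2]},
        "cv": ds.cv,
        "seed": ds.seed,
        "truth": ds.truth.to_dict(),
        "version": __version__,
    }
    Path(out).write_text(yaml.safe_dump(payload, sort_keys=False))
    click.echo(f"synthetic dataset written to {out}")


def main():
    cli(prog_name="korab")


if __name__ == "__main__":
    main()
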