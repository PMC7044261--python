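"""Configuration-driven entry points wiring the modules into full runs.

Each run mode (simulate-psychophysics, simulate-eeg, fit,
reproduce-table1) reads a :class:`RunConfig`, executes the corresponding
library calls, and writes its outputs plus a JSON manifest (seed,
parameters, design) sufficient to regenerate the artifacts bit-for-bit.
A thin ``click`` command group exposes the same four modes from the
shell; the numbered drivers under ``analysis/`` are the narrative
interface for the full study reproduction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import click
import yaml

from . import fitting, observer, ssaep
from .fitting import FitSpec, evaluate_fixed, fit_dipper, fit_eeg, table1_report
from .observer import DipperDataset, StaircaseConfig, simulate_experiment
from .params import TABLE1, ModelParams, load_params
from .ssaep import EEGResponseDataset, simulate_eeg_experiment

__all__ = [
    "RunConfig",
    "run_simulate_psychophysics",
    "run_simulate_eeg",
    "run_fit",
    "run_reproduce_table1",
    "cli",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible run: seed, parameter source, design, paths."""

    mode: str = "simulate-psychophysics"
    seed: int = 0
    out_dir: str = "results"
    fixture: Optional[str] = "6a"
    params_file: Optional[str] = None
    data_path: Optional[str] = None
    model: str = "gain"
    fix: dict = field(default_factory=dict)
    # design overrides
    pedestals: Optional[list] = None
    depths: Optional[list] = None
    n_reps: Optional[int] = None
    n_participants: Optional[int] = None
    noise_sd: float = 1.0
    n_restarts: int = 20
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def true_params(self) -> ModelParams:
        if self.params_file:
            return load_params(self.params_file)
        if self.fixture:
            if self.fixture not in TABLE1:
                raise KeyError(
                    f"unknown fixture {self.fixture!r}; available: {sorted(TABLE1)}"
                )
            return load_params(self.fixture)
        raise ValueError("config needs either 'fixture' or 'params_file'")


def _prepare_out(cfg: RunConfig, stem: str) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / f"{stem}_manifest.json"
    if manifest.exists() and not cfg.overwrite:
        raise FileExistsError(
            f"{manifest} exists; set overwrite: true to replace this run"
        )
    return out


def _write_manifest(out: Path, stem: str, cfg: RunConfig, extra: dict) -> None:
    payload = {"config": asdict(cfg), **extra}
    with open(out / f"{stem}_manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")


def run_simulate_psychophysics(cfg: RunConfig) -> DipperDataset:
    """Simulate the discrimination experiment; write thresholds + trial log."""
    params = cfg.true_params()
    pedestals = tuple(cfg.pedestals) if cfg.pedestals else observer.PEDESTALS
    n_reps = cfg.n_reps or 3
    n_participants = cfg.n_participants or 6
    out = _prepare_out(cfg, "dipper")
    ds, trials = simulate_experiment(
        params, StaircaseConfig(), n_reps=n_reps, n_participants=n_participants,
        rng_seed=cfg.seed, pedestals=pedestals, model=cfg.model, return_trials=True,
    )
    ds.to_csv(out / "dipper_thresholds.csv")
    trials = trials.rename(columns={"pedestal": "pedestal_pct", "target": "target_pct"})
    trials["seed"] = cfg.seed
    trials.to_csv(out / "dipper_trials.csv", index=False)
    _write_manifest(out, "dipper", cfg, {
        "params": params.to_dict(),
        "n_trials": int(len(trials)),
        "outputs": ["dipper_thresholds.csv", "dipper_trials.csv"],
    })
    logger.info("simulate-psychophysics: seed=%s cells=%s trials=%s",
                cfg.seed, len(ds.df), len(trials))
    return ds


def run_simulate_eeg(cfg: RunConfig) -> EEGResponseDataset:
    """Simulate the steady-state EEG experiment; write the SNR table."""
    params = cfg.true_params()
    depths = tuple(cfg.depths) if cfg.depths else ssaep.EEG_DEPTHS
    n_reps = cfg.n_reps or 10
    n_participants = cfg.n_participants or 12
    out = _prepare_out(cfg, "eeg")
    ds = simulate_eeg_experiment(
        params, noise_sd=cfg.noise_sd, n_participants=n_participants,
        n_reps=n_reps, rng_seed=cfg.seed, depths=depths,
    )
    ds.to_csv(out / "eeg_snr.csv")
    _write_manifest(out, "eeg", cfg, {
        "params": params.to_dict(),
        "outputs": ["eeg_snr.csv"],
    })
    logger.info("simulate-eeg: seed=%s cells=%s", cfg.seed, len(ds.df))
    return ds


def _load_dataset(path: str):
    import pandas as pd

    df = pd.read_csv(path)
    if "freq_hz" in df.columns:
        return EEGResponseDataset(df, n_participants=df.get("n_participants", 1).max())
    return DipperDataset(df, n_participants=1)


def run_fit(cfg: RunConfig) -> fitting.FitResult:
    """Fit one model configuration to a dataset file; write FitResult JSON."""
    if not cfg.data_path:
        raise ValueError(
            "fit mode needs data_path; generate data with "
            "simulate-psychophysics or simulate-eeg first"
        )
    data = _load_dataset(cfg.data_path)
    out = _prepare_out(cfg, f"fit_{cfg.model}")
    spec = FitSpec(
        model=cfg.model, fixed=dict(cfg.fix), n_restarts=cfg.n_restarts,
        seed=cfg.seed, with_sigma35=isinstance(data, EEGResponseDataset),
    )
    fit = (fit_eeg if isinstance(data, EEGResponseDataset) else fit_dipper)(data, spec)
    fit.to_json(out / f"fit_{cfg.model}.json")
    _write_manifest(out, f"fit_{cfg.model}", cfg, {"rmse": fit.rmse, "units": fit.units})
    logger.info("fit: model=%s rmse=%.4g %s", cfg.model, fit.rmse, fit.units)
    return fit


#: the eight canonical fit/evaluation configurations of the comparison table
TABLE1_CONFIGS = ("6a", "6b", "6c", "6d", "6e", "6f", "7a", "7b")


def reproduce_table1(
    dipper_data: DipperDataset,
    eeg_data: EEGResponseDataset,
    seed: int = 0,
    n_restarts: int = 20,
):
    """Run the eight-row model comparison on a pair of datasets.

    Rows: free gain-control fit (6a/6d), suppression forced to 1 with
    other parameters kept (6b/6e), refit with suppression fixed at 1
    (6c/6f), and free linear-summation fits (7a/7b); dipper rows use dB
    RMSE, EEG rows SNR RMSE.
    """
    fits: dict[str, fitting.FitResult] = {}
    fits["6a"] = fit_dipper(dipper_data, FitSpec(n_restarts=n_restarts, seed=seed))
    fits["6b"] = evaluate_fixed(fits["6a"].params, {"omega": 1.0}, dipper_data)
    fits["6c"] = fit_dipper(
        dipper_data, FitSpec(fixed={"omega": 1.0}, n_restarts=n_restarts, seed=seed + 1)
    )
    fits["6d"] = fit_eeg(
        eeg_data, FitSpec(n_restarts=n_restarts, seed=seed + 2, with_sigma35=True)
    )
    fits["6e"] = evaluate_fixed(fits["6d"].params, {"omega": 1.0}, eeg_data)
    fits["6f"] = fit_eeg(
        eeg_data,
        FitSpec(fixed={"omega": 1.0}, n_restarts=n_restarts, seed=seed + 3,
                with_sigma35=True),
    )
    fits["7a"] = fit_dipper(
        dipper_data, FitSpec(model="linear", n_restarts=n_restarts, seed=seed + 4)
    )
    fits["7b"] = fit_eeg(
        eeg_data,
        FitSpec(model="linear", n_restarts=n_restarts, seed=seed + 5,
                with_sigma35=True),
    )
    return fits


def run_reproduce_table1(cfg: RunConfig) -> "object":
    """Full comparison on dataset files; write the table + per-fit JSON."""
    out = _prepare_out(cfg, "table1")
    dipper_path = Path(cfg.out_dir) / "dipper_thresholds.csv"
    eeg_path = Path(cfg.out_dir) / "eeg_snr.csv"
    if cfg.data_path:
        base = Path(cfg.data_path)
        dipper_path = base / "dipper_thresholds.csv"
        eeg_path = base / "eeg_snr.csv"
    for path, generator in ((dipper_path, "simulate-psychophysics"),
                            (eeg_path, "simulate-eeg")):
        if not path.exists():
            raise FileNotFoundError(
                f"{path} missing; generate it with `binsum {generator}` first"
            )
    dipper = DipperDataset.from_csv(dipper_path)
    eeg = EEGResponseDataset.from_csv(eeg_path)
    fits = reproduce_table1(dipper, eeg, seed=cfg.seed, n_restarts=cfg.n_restarts)
    table = table1_report(fits)
    table.to_csv(out / "model_comparison.csv", index=False)
    for name, fit in fits.items():
        fit.to_json(out / f"fit_{name}.json")
    # prediction curves for plotting
    curves = {}
    for name in ("6a", "6c", "7a"):
        curves[name] = {
            str(k): v for k, v in fitting.dipper_predictions(
                fits[name].params, fits[name].model, tuple(dipper.pedestals)
            ).items()
        }
    with open(out / "table1_prediction_curves.json", "w") as fh:
        json.dump(curves, fh, indent=2)
        fh.write("\n")
    _write_manifest(out, "table1", cfg, {
        "rows": {k: f.rmse for k, f in fits.items()},
    })
    logger.info("reproduce-table1: %s", {k: round(f.rmse, 3) for k, f in fits.items()})
    return fits


_MODES = {
    "simulate-psychophysics": run_simulate_psychophysics,
    "simulate-eeg": run_simulate_eeg,
    "fit": run_fit,
    "reproduce-table1": run_reproduce_table1,
}


def _common_options(fn):
    opts = [
        click.option("--config", "config_path", type=click.Path(exists=True),
                     default=None, help="YAML run configuration"),
        click.option("--seed", type=int, default=None),
        click.option("--out", "out_dir", type=click.Path(), default=None),
        click.option("--fixture", type=str, default=None,
                     help=f"named parameter set, one of {sorted(TABLE1)}"),
        click.option("--data", "data_path", type=click.Path(), default=None),
        click.option("--model", type=click.Choice(["gain", "linear"]), default=None),
        click.option("--fix", "fix_opts", multiple=True,
                     help="fix a parameter, e.g. --fix omega=1"),
        click.option("--overwrite/--no-overwrite", default=None),
    ]
    for opt in reversed(opts):
        fn = opt(fn)
    return fn


def _build_config(mode, config_path, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    cfg.mode = mode
    fix_opts = overrides.pop("fix_opts", ())
    if fix_opts:
        cfg.fix = {
            k.strip(): float(v) for k, v in (s.split("=", 1) for s in fix_opts)
        }
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    return cfg


@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose):
    """Binaural amplitude-modulation combination: simulate, fit, compare."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _register(mode: str) -> None:
    @cli.command(name=mode)
    @_common_options
    def _cmd(config_path, fix_opts, **overrides):
        cfg = _build_config(mode, config_path, fix_opts=fix_opts, **overrides)
        try:
            _MODES[mode](cfg)
        except FileNotFoundError as exc:
            raise click.ClickException(f"missing-input: {exc}")
        except FileExistsError as exc:
            raise click.ClickException(f"would-overwrite: {exc}")
        except (KeyError, ValueError) as exc:
            raise click.ClickException(f"invalid-config: {exc}")

    _cmd.__doc__ = _MODES[mode].__doc__


for _mode in _MODES:
    _register(_mode)
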