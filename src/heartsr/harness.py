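"""Experiment orchestration: validation, resolution sweeps, end-to-end runs.

All randomness flows from one master seed through named substreams (phantom
data, weight init, shuffling), so each stage is independently reproducible
and a whole run can be re-executed bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PairedDataset
from .degrade import DegradationSpec, degrade_pair
from .metrics import mse as _mse
from .metrics import ssim as _ssim
from .model import Network, NetworkConfig, build_network, super_resolve
from .phantom import PhantomSpec, default_phantom_spec, make_dataset
from .train import TrainConfig, fit
from .volume import Volume

__all__ = [
    "SweepResult",
    "RunConfig",
    "validate",
    "generalisability_sweep",
    "end_to_end",
    "derive_seeds",
]

log = logging.getLogger(__name__)


def derive_seeds(master_seed: int, names=("data", "init", "shuffle", "test")) -> dict[str, int]:
    """Named substreams below 2**31, derived deterministically from one seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(names, children)}


# ---------------------------------------------------------------------------
# validation


def validate(net: Network, testset: PairedDataset) -> dict:
    """Score a network on held-out pairs.

    Reports per-subject SSIM/MSE of low-vs-high and super-resolved-vs-high,
    cohort mean +/- sd, and paired improvement deltas.  Raises if the test
    set is empty or shares items with the network's training provenance.
    """
    if len(testset) == 0:
        raise ValueError("test set is empty")
    train_ids = set(net.provenance.get("train_item_ids", []))
    overlap = train_ids & {it.item_id for it in testset if it.item_id}
    if overlap:
        raise ValueError(f"test items overlap the training set: {sorted(overlap)}")

    rows = []
    for it in testset:
        sr = super_resolve(net, it.lr)
        # score the low-resolution input at the network's working precision
        # (float32), so an identity network scores exactly equal
        lr32 = np.asarray(it.lr.data, dtype=np.float32).astype(np.float64)
        lr_vol = Volume(lr32, spacing=it.lr.spacing)
        rows.append(
            {
                "item_id": it.item_id,
                "ssim_lr": _ssim(lr_vol, it.hr),
                "ssim_sr": _ssim(sr, it.hr),
                "mse_lr": _mse(lr_vol, it.hr),
                "mse_sr": _mse(sr, it.hr),
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "n": int(len(df)),
        "per_subject": rows,
        "ssim_lr_mean": float(df.ssim_lr.mean()),
        "ssim_lr_sd": float(df.ssim_lr.std(ddof=1)) if len(df) > 1 else 0.0,
        "ssim_sr_mean": float(df.ssim_sr.mean()),
        "ssim_sr_sd": float(df.ssim_sr.std(ddof=1)) if len(df) > 1 else 0.0,
        "mse_lr_mean": float(df.mse_lr.mean()),
        "mse_lr_sd": float(df.mse_lr.std(ddof=1)) if len(df) > 1 else 0.0,
        "mse_sr_mean": float(df.mse_sr.mean()),
        "mse_sr_sd": float(df.mse_sr.std(ddof=1)) if len(df) > 1 else 0.0,
        "ssim_improvement": float((df.ssim_sr - df.ssim_lr).mean()),
        "mse_improvement": float((df.mse_lr - df.mse_sr).mean()),
    }
    return summary


# ---------------------------------------------------------------------------
# generalisability sweep


@dataclass
class SweepResult:
    """SSIM/MSE of super-resolved output versus input resolution fraction."""

    records: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fr = [r["fraction"] for r in self.records]
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("sweep fractions must be strictly increasing")
        ns = {r["n"] for r in self.records}
        if len(ns) > 1:
            raise ValueError("sweep records must share the same subject count")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def best_fraction(self, by: str = "ssim_mean") -> float:
        return max(self.records, key=lambda r: r[by])["fraction"]


def generalisability_sweep(
    net: Network,
    highres_set: list[Volume],
    fractions,
    spec_template: DegradationSpec,
) -> SweepResult:
    """Degrade every volume at each resolution fraction (phase and slice
    together, partial Fourier held at the template value), super-resolve,
    and aggregate SSIM/MSE against truth per subject then across subjects.

    Fractions that violate the minimum retained-line rule are skipped with a
    warning and recorded in the provenance.
    """
    fractions = sorted(float(f) for f in fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    records = []
    skipped = []
    for f in fractions:
        spec = dataclasses.replace(spec_template, phase_fraction=f, slice_fraction=f)
        ssims, mses = [], []
        try:
            for vol in highres_set:
                hr, lr = degrade_pair(vol, spec)
                sr = super_resolve(net, lr)
                ssims.append(_ssim(sr, hr))
                mses.append(_mse(sr, hr))
        except ValueError as exc:
            log.warning("sweep: skipping fraction %.3f (%s)", f, exc)
            skipped.append({"fraction": f, "reason": str(exc)})
            continue
        records.append(
            {
                "fraction": f,
                "ssim_mean": float(np.mean(ssims)),
                "ssim_sd": float(np.std(ssims, ddof=1)) if len(ssims) > 1 else 0.0,
                "mse_mean": float(np.mean(mses)),
                "mse_sd": float(np.std(mses, ddof=1)) if len(mses) > 1 else 0.0,
                "n": len(ssims),
            }
        )
    return SweepResult(
        records=records,
        provenance={
            "degradation_template": spec_template.to_dict(),
            "skipped": skipped,
            "trained_fraction": net.provenance.get("trained_fraction"),
        },
    )


# ---------------------------------------------------------------------------
# end-to-end runs


@dataclass
class RunConfig:
    """One seeded simulate -> train -> validate -> sweep experiment."""

    out_dir: str
    master_seed: int = 0
    n_train: int = 8
    n_test: int = 4
    matrix: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.6, 1.6, 1.6)
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    net: NetworkConfig = field(default_factory=lambda: NetworkConfig(levels=2, base_channels=8))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=30))
    sweep_fractions: tuple[float, ...] = (0.3, 0.5, 0.7)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "master_seed": self.master_seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "matrix": list(self.matrix),
            "spacing": list(self.spacing),
            "degradation": self.degradation.to_dict(),
            "net": self.net.to_dict(),
            "train": self.train.to_dict(),
            "sweep_fractions": list(self.sweep_fractions),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["matrix"] = tuple(d.get("matrix", (48, 48, 48)))
        d["spacing"] = tuple(d.get("spacing", (1.6, 1.6, 1.6)))
        d["degradation"] = DegradationSpec.from_dict(d.get("degradation", {}))
        d["net"] = NetworkConfig.from_dict(d.get("net", {}))
        d["train"] = TrainConfig(**d.get("train", {}))
        d["sweep_fractions"] = tuple(d.get("sweep_fractions", (0.3, 0.5, 0.7)))
        return cls(**d)


def _stage(logf, name: str, t0: float, **extra) -> None:
    rec = {"stage": name, "elapsed_s": round(time.perf_counter() - t0, 3), **extra}
    logf.write(json.dumps(rec, sort_keys=True) + "\n")
    logf.flush()
    log.info("stage %s done (%.1fs)", name, rec["elapsed_s"])


def end_to_end(run: RunConfig) -> Path:
    """Execute the full seeded pipeline and persist every artifact.

    Writes manifest.json, dataset.h5, testset.h5, checkpoint.npz,
    train_report.json, loss_trace.csv, validation.json, sweep.csv and
    log.jsonl under ``run.out_dir``; returns that directory.  Any stage
    failure re-raises with the stage name, leaving a partial manifest.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(run.master_seed)
    manifest = {"run": run.to_dict(), "seeds": seeds, "stages_done": []}

    def save_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    save_manifest()
    t0 = time.perf_counter()
    stage = "simulate"
    with open(out / "log.jsonl", "w") as logf:
        try:
            template = default_phantom_spec(run.matrix, run.spacing)
            train_ds = make_dataset(
                template, run.n_train, seeds["data"], run.degradation, role="train",
                path=out / "dataset.h5",
            )
            test_ds = make_dataset(
                template, run.n_test, seeds["test"], run.degradation, role="test",
                path=out / "testset.h5",
            )
            manifest["stages_done"].append(stage)
            save_manifest()
            _stage(logf, stage, t0, n_train=len(train_ds), n_test=len(test_ds))

            stage = "train"
            net_cfg = dataclasses.replace(run.net, seed=seeds["init"])
            train_cfg = dataclasses.replace(run.train, seed=seeds["shuffle"])
            net, report = fit(train_ds, net_cfg, train_cfg, checkpoint_path=out / "checkpoint.npz")
            net.provenance["trained_fraction"] = run.degradation.phase_fraction
            net.save(out / "checkpoint.npz")
            report.save(out / "train_report.json")
            pd.DataFrame({"epoch": range(1, len(report.epoch_loss) + 1), "loss": report.epoch_loss}).to_csv(
                out / "loss_trace.csv", index=False
            )
            manifest["stages_done"].append(stage)
            save_manifest()
            _stage(logf, stage, t0, final_loss=report.epoch_loss[-1])

            stage = "validate"
            summary = validate(net, test_ds)
            (out / "validation.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
            manifest["stages_done"].append(stage)
            save_manifest()
            _stage(logf, stage, t0, ssim_sr_mean=summary["ssim_sr_mean"])

            stage = "sweep"
            hi_res = _regenerate_hr(template, seeds["test"], run.n_test)
            sweep = generalisability_sweep(net, hi_res, run.sweep_fractions, run.degradation)
            sweep.to_dataframe().to_csv(out / "sweep.csv", index=False)
            manifest["stages_done"].append(stage)
            save_manifest()
            _stage(logf, stage, t0, n_fractions=len(sweep.records))
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            save_manifest()
            raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    return out


def _regenerate_hr(template: PhantomSpec, seed: int, n: int) -> list[Volume]:
    """Re-create the raw high-resolution test phantoms (pre-degradation)."""
    from .phantom import generate_phantom, jitter_spec

    vols = []
    for child in np.random.SeedSequence(seed).spawn(n):
        item_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(item_seed)
        spec_i = jitter_spec(template, rng, 0.1, seed=item_seed)
        vol, _, _ = generate_phantom(spec_i)
        vols.append(vol)
    return vols


def rerun_from_manifest(manifest_path) -> Path:
    """Re-execute a run from its persisted manifest (bit-identical)."""
    manifest = json.loads(Path(manifest_path).read_text())
    return end_to_end(RunConfig.from_dict(manifest["run"]))
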