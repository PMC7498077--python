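"""Model validation by relative root-mean-square error on root depths.

RRMSE compares measured depths OBS_i with simulated depths SIM_i:

    RRMSE = 100 * sqrt( (1/n) * sum (OBS_i - SIM_i)^2 ) / ( (1/n) * sum OBS_i )

and is mapped onto a four-level accuracy scale: below 10 % the agreement is
extremely significant, 10-20 % significant, 20-30 % general, and at or above
30 % poor (boundaries go to the worse class).

``validate_model`` runs the full loop: simulate plants from a parameter
database, take each root's trajectory-derived maximum depth, and pair the
simulated depth distribution with the measured one per root class.  Field
plants and simulated plants carry no shared identity, so pairing is by rank:
both vectors are compared quantile-to-quantile.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .database import ROOT_CLASSES, ParameterDatabase
from .topology import build_plant

__all__ = [
    "PairedSample",
    "ValidationReport",
    "rrmse",
    "classify_rrmse",
    "validate_model",
]

LEVELS = ("extremely_significant", "significant", "general", "poor")


@dataclass
class PairedSample:
    """Observed/simulated value pairs for one organ class."""

    obs: np.ndarray
    sim: np.ndarray
    organ_class: str = ""
    variety: str = ""

    def __post_init__(self):
        self.obs = np.asarray(self.obs, float)
        self.sim = np.asarray(self.sim, float)
        if self.obs.shape != self.sim.shape or self.obs.ndim != 1:
            raise ValueError(
                f"obs and sim must be equal-length vectors, got "
                f"{self.obs.shape} and {self.sim.shape}"
            )
        if self.obs.size < 1:
            raise ValueError("need at least one observed/simulated pair")


def rrmse(pair: PairedSample) -> float:
    """Relative root-mean-square error, in percent."""
    mean_obs = pair.obs.mean()
    if mean_obs <= 0:
        raise ValueError(
            f"mean of observations is {mean_obs}; the relative scale is "
            "undefined for non-positive means"
        )
    rms = np.sqrt(np.mean((pair.obs - pair.sim) ** 2))
    return float(100.0 * rms / mean_obs)


def classify_rrmse(value: float) -> str:
    """Four-level accuracy verdict; boundary values go to the worse class."""
    if value < 0:
        raise ValueError(f"RRMSE cannot be negative, got {value}")
    if value < 10:
        return "extremely_significant"
    if value < 20:
        return "significant"
    if value < 30:
        return "general"
    return "poor"


@dataclass
class ValidationReport:
    """Per (variety, organ class) RRMSE results plus the paired vectors."""

    variety: str
    seed: int | None
    entries: dict[str, dict] = field(default_factory=dict)
    pairs: dict[str, PairedSample] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variety": self.variety, "organ_class": oc, **e}
            for oc, e in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "variety": self.variety,
            "seed": self.seed,
            "results": self.entries,
            "pairs": {
                oc: {"obs": p.obs.tolist(), "sim": p.sim.tolist()}
                for oc, p in self.pairs.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        """Measured-vs-simulated scatter per root class (one panel each)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        classes = list(self.pairs)
        fig, axes = plt.subplots(1, len(classes),
                                 figsize=(4 * len(classes), 4))
        for ax, oc in zip(np.atleast_1d(axes), classes):
            p = self.pairs[oc]
            lim = max(p.obs.max(), p.sim.max()) * 1.05
            ax.scatter(p.obs, p.sim, s=12)
            ax.plot([0, lim], [0, lim], "k--", lw=0.8)
            ax.set_xlabel("measured depth (mm)")
            ax.set_ylabel("simulated depth (mm)")
            ax.set_title(
                f"{oc}: RRMSE {self.entries[oc]['rrmse_percent']:.2f}%"
            )
        fig.suptitle(self.variety)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _rank_pair(obs: np.ndarray, sim: np.ndarray) -> PairedSample:
    """Quantile-match two depth samples of possibly different size."""
    obs_sorted = np.sort(obs)
    n = len(obs_sorted)
    q = (np.arange(n) + 0.5) / n
    sim_q = np.quantile(sim, q)
    return PairedSample(obs=obs_sorted, sim=sim_q)


def validate_model(
    db: ParameterDatabase,
    measured: pd.DataFrame,
    n_plants: int = 50,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    l_unit: float = 1.0,
) -> ValidationReport:
    """Simulate ``n_plants`` plants and compare root depths per class.

    Measured depths come from the ``depth_mm`` rows of the measurement
    table; simulated depths are trajectory-derived (maximum depth of each
    generated axis), so the comparison exercises the whole growth model, not
    just the fitted depth distribution.  Classes missing on either side are
    skipped with a warning.
    """
    if n_plants < 1:
        raise ValueError(f"n_plants must be >= 1, got {n_plants}")
    if rng is None:
        rng = np.random.default_rng(seed)

    sim_depths: dict[str, list[float]] = {oc: [] for oc in ROOT_CLASSES}
    for _ in range(n_plants):
        plant = build_plant(db, rng=rng, l_unit=l_unit)
        for oc in ROOT_CLASSES:
            sim_depths[oc].extend(plant.depths_by_class(oc))

    report = ValidationReport(variety=db.variety, seed=seed)
    depth_rows = measured[measured["parameter"] == "depth_mm"]
    for oc in ROOT_CLASSES:
        obs = depth_rows.loc[
            depth_rows["organ_class"] == oc, "value"
        ].to_numpy(float)
        sim = np.asarray(sim_depths[oc])
        if len(obs) == 0 or len(sim) == 0:
            warnings.warn(
                f"no {'measured' if len(obs) == 0 else 'simulated'} depths "
                f"for {oc}; class skipped",
                stacklevel=2,
            )
            continue
        pair = _rank_pair(obs, sim)
        pair.organ_class, pair.variety = oc, db.variety
        value = rrmse(pair)
        report.pairs[oc] = pair
        report.entries[oc] = {
            "rrmse_percent": value,
            "level": classify_rrmse(value),
            "n": int(len(pair.obs)),
        }
    return report
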