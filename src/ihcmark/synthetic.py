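"""Synthetic biomarker cohorts with planted response and survival effects.

Emulates the kind of dataset the downstream analysis assumes: a small
head-and-neck cancer cohort (default n = 37) where each patient carries a
response category (CR/PR/SD/PD), an overall-survival time with censoring
indicator, and, per marker x subcellular compartment, both machine-style
intensity-bin fractions (with their H-score) and pathologist-style ordinal
grades (Q, I, IxQ).

Generative model
----------------
Each marker has a latent expression score on the 0-300 H-score scale,
drawn per its location/scale spec. Let ``z`` be the population-standardized
latent score. Then

* machine bin fractions are a Gaussian-kernel softmax over the 0/1+/2+/3+
  bin centers of the latent intensity (latent/100), so the derived H-score
  tracks the latent score smoothly;
* pathologist grades are recomputed from the bin fractions (percent
  positive -> Q, mean stained intensity -> I), optionally with additive
  jitter emulating inter-observer noise;
* the probability of *non-response* (SD/PD) follows a logistic model whose
  log-odds shift by ``response_effect * z`` summed over markers;
* event times are exponential with hazard
  ``baseline_hazard * exp(sum(log_hazard_ratio * z))``, censoring times
  independently exponential with rate ``censoring_rate``; the recorded time
  is the minimum of the two.

A single seeded generator drives every draw in a fixed order, so a config
plus seed reproduces the table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .scoring import quantity_bin

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "generate_cohort",
    "marker_column",
    "default_cohort_config",
    "write_cohort",
    "read_cohort",
    "write_config",
    "read_config",
]

#: Softmax kernel width (latent-intensity units) for the bin-fraction model.
BIN_SOFTMAX_WIDTH = 0.6
_BIN_CENTERS = np.array([0.0, 1.0, 2.0, 3.0])

#: Uniform latent spanning the full 0-300 scale: sd = 300 / sqrt(12).
_UNIFORM_FULL_SCALE_SD = float(300.0 / 12.0 ** 0.5)


@dataclass
class MarkerSpec:
    """Latent-score distribution and planted effects for one marker.

    ``location``/``scale`` are the population mean and standard deviation
    of the latent score (H-score units). ``response_effect`` is the
    log-odds shift toward non-response per standard deviation of latent
    score; ``log_hazard_ratio`` the log hazard ratio per standard
    deviation. ``distribution`` is "uniform" (bounded, spanning
    location +/- sqrt(3)*scale) or "normal" (clipped to [0, 300]).
    """

    name: str
    compartment: str = "nuclear"
    location: float = 150.0
    scale: float = _UNIFORM_FULL_SCALE_SD
    distribution: str = "uniform"
    response_effect: float = 0.0
    log_hazard_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.compartment not in ("nuclear", "cytoplasmic"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort draw."""

    n_patients: int = 37
    #: P(CR), P(PR), P(SD) and optionally P(PD); must sum to 1.
    response_probs: tuple[float, ...] = (11 / 37, 19 / 37, 7 / 37)
    markers: list[MarkerSpec] = field(default_factory=lambda: [MarkerSpec("marker1")])
    baseline_hazard: float = 0.02  # events per month
    censoring_rate: float = 0.01  # censorings per month; 0 disables
    pathologist_jitter: float = 0.0  # sd of additive noise on pct/intensity
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.response_probs, dtype=float)
        if p.size not in (3, 4):
            raise ValueError("response_probs must have 3 (CR,PR,SD) or 4 (+PD) entries")
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("response probabilities must lie in [0,1] and sum to 1")
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")
        if not self.markers:
            raise ValueError("at least one marker spec is required")


def marker_column(spec: MarkerSpec) -> str:
    """Column prefix for a marker: name, with ``_cyt`` for cytoplasmic."""
    return spec.name if spec.compartment == "nuclear" else f"{spec.name}_cyt"


def _bin_fractions(latent: np.ndarray) -> np.ndarray:
    """(n, 4) softmax bin fractions from latent scores on [0, 300]."""
    u = latent[:, None] / 100.0
    logits = -((u - _BIN_CENTERS[None, :]) ** 2) / (2.0 * BIN_SOFTMAX_WIDTH ** 2)
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    return w / w.sum(axis=1, keepdims=True)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one cohort table. Deterministic given ``config.seed``.

    Columns: ``patient_id``, ``response``, ``responder``, ``time_months``,
    ``event``, then per marker ``<m>_score`` (latent), ``<m>_f0..f3``,
    ``<m>_hscore``, ``<m>_pct_pos``, ``<m>_Q``, ``<m>_I``, ``<m>_IxQ``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    cols: dict[str, np.ndarray] = {}
    z_total_response = np.zeros(n)
    z_total_hazard = np.zeros(n)

    for spec in config.markers:
        if spec.distribution == "uniform":
            half = np.sqrt(3.0) * spec.scale
            latent = rng.uniform(spec.location - half, spec.location + half, n)
        else:
            latent = rng.normal(spec.location, spec.scale, n)
        latent = np.clip(latent, 0.0, 300.0)
        z = (latent - spec.location) / spec.scale
        z_total_response += spec.response_effect * z
        z_total_hazard += spec.log_hazard_ratio * z

        f = _bin_fractions(latent)
        hscore = 100.0 * (f[:, 1] + 2.0 * f[:, 2] + 3.0 * f[:, 3])
        pct_pos = 100.0 * (1.0 - f[:, 0])
        stained = f[:, 1:].sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_intensity = (f[:, 1] + 2 * f[:, 2] + 3 * f[:, 3]) / stained
        mean_intensity = np.where(stained > 0, mean_intensity, 0.0)
        if config.pathologist_jitter > 0:
            pct_pos = np.clip(pct_pos + rng.normal(0, config.pathologist_jitter, n), 0, 100)
            mean_intensity = np.clip(
                mean_intensity + rng.normal(0, config.pathologist_jitter / 100.0, n),
                0, 3)
        q = np.array([quantity_bin(p) for p in pct_pos])
        i = np.where(pct_pos > 0, np.clip(np.rint(mean_intensity), 1, 3), 0).astype(int)

        m = marker_column(spec)
        cols[f"{m}_score"] = latent
        for k in range(4):
            cols[f"{m}_f{k}"] = f[:, k]
        cols[f"{m}_hscore"] = hscore
        cols[f"{m}_pct_pos"] = pct_pos
        cols[f"{m}_Q"] = q
        cols[f"{m}_I"] = i
        cols[f"{m}_IxQ"] = q * i

    # Response category: logistic model for responder vs non-responder,
    # category split within each arm per the marginal probabilities.
    p = np.asarray(config.response_probs, dtype=float)
    p_cr, p_pr = p[0], p[1]
    p_sd = p[2]
    p_pd = p[3] if p.size == 4 else 0.0
    p_nonresp = p_sd + p_pd
    eta = np.log(p_nonresp / (1.0 - p_nonresp)) + z_total_response
    nonresponder = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    u = rng.random(n)
    response = np.where(
        nonresponder,
        np.where(u < (p_sd / p_nonresp if p_nonresp > 0 else 1.0), "SD", "PD"),
        np.where(u < p_cr / (p_cr + p_pr), "CR", "PR"),
    )

    # Survival: exponential event times under proportional hazards,
    # independent exponential censoring.
    hazard = config.baseline_hazard * np.exp(z_total_hazard)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    width = len(str(n))
    table = {
        "patient_id": [f"P{i + 1:0{width}d}" for i in range(n)],
        "response": response,
        "responder": ~nonresponder,
        "time_months": time,
        "event": event,
    }
    table.update(cols)
    return pd.DataFrame(table)


def default_cohort_config(seed: int = 0) -> SimulationConfig:
    """Study-shaped default: 37 patients, 11/19/7 CR/PR/SD marginals,
    eight DNA-repair markers (pMK2 scored in both compartments), a planted
    response effect on XPF (high expression -> worse response) and a
    planted survival effect on nuclear pMK2 (high expression -> higher
    hazard); the remaining markers are null.
    """
    markers = [
        MarkerSpec("XPF", response_effect=1.2),
        MarkerSpec("ERCC1"),
        MarkerSpec("pMK2", log_hazard_ratio=0.8),
        MarkerSpec("pMK2", compartment="cytoplasmic"),
        MarkerSpec("MLH1"),
        MarkerSpec("PARP1"),
        MarkerSpec("PAR"),
        MarkerSpec("FANCD2"),
        MarkerSpec("gH2AX"),
    ]
    return SimulationConfig(markers=markers, seed=seed)


# ---------------------------------------------------------------------------
# Plain-text I/O

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(config: SimulationConfig, path) -> None:
    """Flat key-value text (YAML mapping); markers as a list of mappings."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    markers = [MarkerSpec(**m) for m in raw.pop("markers")]
    raw["response_probs"] = tuple(raw["response_probs"])
    return SimulationConfig(markers=markers, **raw)
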