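"""Synthetic microcosm panels with known ground truth.

Generates the full shape of the pH-perturbation study — 20 soils spanning
native pH 4.7–8.3, 13 perturbed pH levels between 3 and 9, triplicate
CHL-/CHL+ nitrate time series on the 0–91 h grid with 2 mM initial nitrate,
per-soil titration curves, and ASV count tables with two internal-standard
spike-ins — so that every pipeline stage can be tested against planted
truth without any external data.

Ground-truth surfaces are deterministic functions of the panel spec (seeds
only drive measurement noise), shaped to reproduce the qualitative
structure of the study system:

* functional biomass x~0 sits on a high plateau (0.5 mM/day) around the
  native pH, collapses sharply below an acid-death boundary whose pH rises
  with native pH with slope 0.7, and collapses again once the NaOH dose
  exceeds a fixed threshold (the resurgent-growth transition is driven by
  the amount of base, not by pH itself);
* the limiting nutrient is released in proportion to the NaOH dose
  (C~0 = c_rate * dose), crossing the regime III nutrient threshold at a
  fixed dose for every soil;
* titration curves are logistic in dose with per-soil buffering width, so
  acidic soils (on the lower plateau) are more strongly buffered than
  neutral ones.

Count tables plant phylum-structured growth: rare Firmicutes-like ASVs
that grow only beyond the base-dose threshold (their identity drawn from a
pH-ordered pool, so the growers encode the soil's native pH), dominant
Proteobacteria/Bacteroidota-like ASVs that grow with dose in the
nutrient-limited regime and die under acid, replicate noise following the
two-component model sigma(n) = sqrt((c_frac n)^2 + c0^2) (Gaussian, rounded
to integers, floored at 0), and spike-in reads near 8.9% of the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .abundance import CountTable
from .crm import DEFAULT_GAMMA, DEFAULT_KA, DEFAULT_KC, HOURS_PER_DAY, TIMEPOINTS_HR, CRMParams
from .fitting import simulate_pair
from .regimes import TitrationCurve, classify_regime

__all__ = [
    "SoilPanelSpec",
    "GroundTruth",
    "CountTruth",
    "make_soil_panel",
    "simulate_experiment",
    "simulate_counts",
    "replicate_count_tables",
    "make_presence_panel",
    "titration_dose",
    "titration_ph",
]

# ---------------------------------------------------------------------------
# ground-truth surface constants (package choices; see docs/methods.md)

X_PLATEAU = 0.5     # Regime II biomass plateau, mM/day
X_MIN = 1e-3        # residual biomass outside the plateau, mM/day
ACID_SLOPE = 0.7    # d(boundary pH)/d(native pH) of the acid-death edge
ACID_OFFSET = 0.2   # boundary12 = ACID_SLOPE * native + ACID_OFFSET
ACID_WIDTH = 0.06   # pH width of the acid-side biomass collapse
DOSE_NUTRIENT = 15.0  # NaOH dose where gamma*C~0 crosses the regime III threshold, mM
DOSE_X_COLLAPSE = 19.0  # NaOH dose where the plateau biomass collapses, mM
DOSE_WIDTH = 1.5    # dose width of the basic-side collapse, mM
C_RATE = 1.5 / (DEFAULT_GAMMA * DOSE_NUTRIENT)  # rescaled nutrient per mM NaOH
C_BASE = 0.02       # background nutrient, mM

PH_FLOOR = 2.2      # titration lower plateau
PH_CEIL = 9.6       # titration upper plateau
DOSE_LIMIT = 100.0  # largest acid/base dose titrated, mM

SPIKE_FRACTION = 0.089  # target spike-in share of total reads


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass(frozen=True)
class SoilPanelSpec:
    """Design of the perturbation panel (defaults = the study design)."""

    n_soils: int = 20
    native_ph_range: Tuple[float, float] = (4.7, 8.3)
    n_perturbed: int = 13
    perturbed_ph_range: Tuple[float, float] = (3.0, 9.0)
    replicates: int = 3
    timepoints_hr: Tuple[float, ...] = TIMEPOINTS_HR
    nitrate_mM: float = 2.0
    noise_sd: float = 0.05  # metabolite measurement noise, mM

    def __post_init__(self) -> None:
        if self.n_soils < 1 or self.n_perturbed < 1 or self.replicates < 1:
            raise ValueError("panel dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def _titration_params(spec: SoilPanelSpec) -> pd.DataFrame:
    """Per-soil logistic titration parameters, deterministic in the spec."""
    n = spec.n_soils
    lo, hi = spec.native_ph_range
    native = np.linspace(lo, hi, n) if n > 1 else np.array([0.5 * (lo + hi)])
    # buffering width grows mildly from acidic to basic soils
    s = 20.0 + (12.0 * np.arange(n) / max(n - 1, 1))
    span = PH_CEIL - PH_FLOOR
    frac = (native - PH_FLOOR) / span
    d0 = -s * np.log(frac / (1 - frac))  # dose at the logistic midpoint
    return pd.DataFrame(
        {
            "soil_id": [f"S{i + 1:02d}" for i in range(n)],
            "native_ph": native,
            "titr_scale": s,
            "titr_d0": d0,
        }
    )


def titration_ph(dose: np.ndarray, scale: float, d0: float) -> np.ndarray:
    """Ground-truth endpoint pH after a signed acid/base dose (mM)."""
    return PH_FLOOR + (PH_CEIL - PH_FLOOR) * _sigmoid((np.asarray(dose, float) - d0) / scale)


def titration_dose(ph: float, scale: float, d0: float) -> float:
    """Exact inverse of the ground-truth titration logistic."""
    frac = (ph - PH_FLOOR) / (PH_CEIL - PH_FLOOR)
    if not 0 < frac < 1:
        raise ValueError(f"pH {ph} outside the titratable range")
    return float(d0 + scale * math.log(frac / (1 - frac)))


def _x0_surface(perturbed_ph: float, dose: float, native_ph: float) -> float:
    b12 = ACID_SLOPE * native_ph + ACID_OFFSET
    acid = _sigmoid((perturbed_ph - b12) / ACID_WIDTH)
    basic = _sigmoid((DOSE_X_COLLAPSE - dose) / DOSE_WIDTH)
    return float(X_MIN + X_PLATEAU * acid * basic)


def _c0_surface(dose: float) -> float:
    return float(C_BASE + C_RATE * max(dose, 0.0))


@dataclass
class GroundTruth:
    """Planted panel: per-soil titrations and per-condition model parameters."""

    spec: SoilPanelSpec
    soils: pd.DataFrame       # soil_id, native_ph, titr_scale, titr_d0
    conditions: pd.DataFrame  # soil_id, native_ph, perturbed_ph, dose_mM,
    #                           x0_tilde, C0_tilde, gammaC0_tilde, regime
    seed: int = 0

    def titration_curve(self, soil_id: str, n_points: int = 23) -> TitrationCurve:
        row = self.soils.set_index("soil_id").loc[soil_id]
        doses = np.linspace(-DOSE_LIMIT, DOSE_LIMIT, n_points)
        return TitrationCurve(
            dose_mM=doses,
            endpoint_ph=titration_ph(doses, row["titr_scale"], row["titr_d0"]),
            soil_id=soil_id,
            native_ph=float(row["native_ph"]),
        )

    def params_for(self, soil_id: str, perturbed_ph: float) -> CRMParams:
        c = self.conditions
        row = c[(c["soil_id"] == soil_id) & (np.isclose(c["perturbed_ph"], perturbed_ph))]
        if row.empty:
            raise KeyError(f"no condition {soil_id} @ pH {perturbed_ph}")
        r = row.iloc[0]
        return CRMParams(
            x0_tilde=float(r["x0_tilde"]),
            C0_tilde=float(r["C0_tilde"]),
            A0=self.spec.nitrate_mM,
            A0c=self.spec.nitrate_mM,
            gamma=DEFAULT_GAMMA,
            KA=DEFAULT_KA,
            KC_tilde=DEFAULT_KC,
        )


def make_soil_panel(spec: SoilPanelSpec = SoilPanelSpec(), seed: int = 0) -> GroundTruth:
    """Build the planted panel.  Surfaces depend only on the spec; the seed
    is recorded for downstream noise generation."""
    soils = _titration_params(spec)
    lo, hi = spec.perturbed_ph_range
    targets = np.linspace(lo, hi, spec.n_perturbed)
    rows = []
    for _, s in soils.iterrows():
        native = float(s["native_ph"])
        levels = targets.copy()
        levels[int(np.argmin(np.abs(levels - native)))] = native
        for q in levels:
            if math.isclose(q, native):
                dose = 0.0
            else:
                try:
                    dose = titration_dose(q, float(s["titr_scale"]), float(s["titr_d0"]))
                except ValueError:
                    continue
                if abs(dose) > DOSE_LIMIT:
                    continue  # unreachable for this strongly buffered soil
            x0 = _x0_surface(q, dose, native)
            c0 = _c0_surface(dose)
            label = classify_regime(x0, DEFAULT_GAMMA * c0).regime
            rows.append(
                {
                    "soil_id": s["soil_id"],
                    "native_ph": native,
                    "perturbed_ph": float(q),
                    "dose_mM": dose,
                    "x0_tilde": x0,
                    "C0_tilde": c0,
                    "gammaC0_tilde": DEFAULT_GAMMA * c0,
                    "regime": label,
                }
            )
    conditions = pd.DataFrame(rows).sort_values(["soil_id", "perturbed_ph"]).reset_index(drop=True)
    return GroundTruth(spec=spec, soils=soils, conditions=conditions, seed=seed)


def simulate_experiment(
    truth: GroundTruth, seed: Optional[int] = None, model: str = "numeric"
) -> pd.DataFrame:
    """Tidy table of triplicate CHL+/- nitrate series for every condition.

    Columns: soil_id, native_pH, perturbed_pH, replicate, chl, time_hr,
    nitrate_mM.  Gaussian measurement noise (spec.noise_sd) clipped at 0.
    """
    spec = truth.spec
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    t_hr = np.asarray(spec.timepoints_hr, dtype=float)
    frames = []
    for _, cond in truth.conditions.iterrows():
        params = truth.params_for(cond["soil_id"], cond["perturbed_ph"])
        for rep in range(1, spec.replicates + 1):
            pair = simulate_pair(
                params, times_hr=t_hr, noise_sd=spec.noise_sd, rng=rng, model=model
            )
            for chl, a in ((0, pair.nitrate_minus), (1, pair.nitrate_plus)):
                frames.append(
                    pd.DataFrame(
                        {
                            "soil_id": cond["soil_id"],
                            "native_pH": cond["native_ph"],
                            "perturbed_pH": cond["perturbed_ph"],
                            "replicate": rep,
                            "chl": chl,
                            "time_hr": t_hr,
                            "nitrate_mM": a,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# count tables


def _noisy_counts(
    mean: np.ndarray, c_frac: float, c0: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-component Gaussian count noise, rounded and floored at zero."""
    sigma = np.sqrt((c_frac * mean) ** 2 + c0**2)
    if c_frac == 0 and c0 == 0:
        return np.round(mean)
    return np.clip(np.round(mean + rng.normal(0.0, 1.0, mean.shape) * sigma), 0, None)


def replicate_count_tables(
    mean_counts: np.ndarray,
    n_reps: int = 3,
    c_frac: float = 0.21,
    c0: float = 4.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate count columns around fixed per-ASV means under the noise model.

    The workhorse for noise-model calibration checks: each replicate is an
    independent Gaussian perturbation of the mean with per-measurement
    sd sigma(n) = sqrt((c_frac n)^2 + c0^2), rounded to integer counts.
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(mean_counts, dtype=float)
    data = {f"rep{r + 1}": _noisy_counts(mean, c_frac, c0, rng) for r in range(n_reps)}
    return pd.DataFrame(data, index=[f"ASV{i + 1}" for i in range(mean.size)])


_PHYLA = (
    ("Proteobacteria", 0.30),
    ("Bacteroidota", 0.15),
    ("Firmicutes", 0.10),
    ("Actinobacteriota", 0.15),
    ("Acidobacteriota", 0.10),
    ("Chloroflexi", 0.07),
    ("Verrucomicrobiota", 0.05),
    ("Planctomycetota", 0.04),
    ("Myxococcota", 0.02),
    ("Gemmatimonadota", 0.02),
)


@dataclass
class CountTruth:
    """What was planted in a synthetic count panel."""

    c_frac: float
    c0: float
    spike_asvs: Tuple[str, str]
    growers_by_condition: Dict[Tuple[str, float], Set[str]]
    nn_responders: Set[str]
    firmicutes_centers: pd.Series  # preferred pH of each Firmicutes ASV
    taxonomy: pd.DataFrame


def simulate_counts(
    truth: GroundTruth,
    soil_ids: Optional[Sequence[str]] = None,
    n_asv: int = 2000,
    mean_depth: float = 30.0,
    c_frac: float = 0.15,
    c0: float = 4.5,
    regime3_fold: float = 200.0,
    dose_growth_rate: float = 0.2,
    seed: Optional[int] = None,
) -> Tuple[CountTable, CountTruth]:
    """ASV count tables for T0, endpoint CHL-/+ and no-nitrate controls.

    Returns one CountTable whose metadata distinguishes timepoint ("T0" or
    "end"), chl arm, nitrate presence, soil, perturbed pH and replicate,
    plus the planted truth.  Growth structure:

    * Firmicutes ASVs are rare at T0 and grow ``regime3_fold``-fold in the
      CHL- arm wherever the NaOH dose exceeds the collapse threshold, but
      only those whose preferred pH lies near the soil's native pH are
      present in that soil at all (a pH-ordered pool);
    * Proteobacteria/Bacteroidota ASVs grow (1 + dose_growth_rate * dose)-
      fold in the nutrient-limited regime and die under acid in both arms;
    * two spike-in ASVs receive equal expected counts at ~8.9% of reads;
    * a few planted "no-nitrate responders" grow regardless of nitrate.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    spec = truth.spec
    soils = truth.soils if soil_ids is None else truth.soils[
        truth.soils["soil_id"].isin(soil_ids)
    ]

    asv_ids = np.array([f"ASV{i + 1:05d}" for i in range(n_asv)])
    phyla_names = [p for p, _ in _PHYLA]
    probs = np.array([w for _, w in _PHYLA])
    phyla = rng.choice(phyla_names, size=n_asv, p=probs / probs.sum())
    taxonomy = pd.DataFrame({"phylum": phyla}, index=asv_ids)

    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_asv)
    firmicutes = phyla == "Firmicutes"
    # rare at T0, but above the detection floor so planted growth is callable
    base[firmicutes] = 0.05 * np.clip(base[firmicutes], 4.0, None)
    dominant = (phyla == "Proteobacteria") | (phyla == "Bacteroidota")
    base = base / base.sum()

    lo, hi = spec.native_ph_range
    centers = pd.Series(
        rng.uniform(lo - 0.3, hi + 0.3, size=int(firmicutes.sum())),
        index=asv_ids[firmicutes],
    )
    nn_responders = set(rng.choice(asv_ids[dominant], size=5, replace=False))

    columns: Dict[str, np.ndarray] = {}
    spikes: Dict[str, float] = {}
    meta_rows = []
    growers: Dict[Tuple[str, float], Set[str]] = {}

    spike_amount = {}  # per-soil fixed spike DNA amount (abundance units)
    depth = {}         # per-soil sequencing depth (reads)

    def emit(name, mean_vec, soil, ph, rep, chl, tp, nitrate):
        # reads are compositional: a fixed amount of spike DNA is added to
        # every sample, and expected counts are depth * amount / total, so
        # the spike fraction rises when community biomass falls.  All
        # multiplicative replicate-to-replicate variation (incl. depth) is
        # carried by c_frac, matching how the noise model is calibrated.
        scale = depth[soil] / (mean_vec.sum() + spike_amount[soil])
        counts = _noisy_counts(mean_vec * scale, c_frac, c0, rng)
        spike_mean = 0.5 * spike_amount[soil] * scale
        s1 = _noisy_counts(np.array([spike_mean]), c_frac, c0, rng)[0]
        s2 = _noisy_counts(np.array([spike_mean]), c_frac, c0, rng)[0]
        columns[name] = counts
        spikes[name] = max(s1 + s2, 1.0)
        meta_rows.append(
            {
                "sample_id": name,
                "soil_id": soil,
                "perturbed_pH": ph,
                "replicate": rep,
                "chl": chl,
                "timepoint": tp,
                "nitrate": nitrate,
                "spike1": s1,
                "spike2": s2,
            }
        )

    for _, s in soils.iterrows():
        soil = s["soil_id"]
        native = float(s["native_ph"])
        # soil-specific community: Firmicutes present only near their pH
        present_f = np.ones(n_asv, dtype=bool)
        f_idx = np.where(firmicutes)[0]
        present_f[f_idx] = np.abs(centers.to_numpy() - native) < 0.8
        t0_mean = base * present_f * (n_asv * mean_depth)
        spike_amount[soil] = t0_mean.sum() * SPIKE_FRACTION / (1 - SPIKE_FRACTION)
        depth[soil] = t0_mean.sum() / (1 - SPIKE_FRACTION)

        for rep in range(1, spec.replicates + 1):
            emit(f"{soil}_T0_r{rep}", t0_mean, soil, native, rep, 0, "T0", 1)

        conds = truth.conditions[truth.conditions["soil_id"] == soil]
        for _, cond in conds.iterrows():
            ph = float(cond["perturbed_ph"])
            dose = float(cond["dose_mM"])
            # survival under acid (both arms), sparing Firmicutes
            b12 = ACID_SLOPE * native + ACID_OFFSET
            surv = 0.05 + 0.95 * _sigmoid((ph - (b12 - 0.25)) / 0.4)
            survival = np.where(firmicutes, 1.0, surv)
            plus_mean = t0_mean * survival

            growth = np.ones(n_asv)
            if cond["regime"] == "II" and 0 <= dose <= 25:
                growth[dominant] = 1.0 + dose_growth_rate * dose
            if dose > DOSE_X_COLLAPSE:
                growth[firmicutes & present_f] = regime3_fold
            grown = growth > 1.0
            if grown.any():
                growers[(soil, ph)] = set(asv_ids[grown])
            minus_mean = plus_mean * growth

            for rep in range(1, spec.replicates + 1):
                emit(f"{soil}_pH{ph:.2f}_r{rep}_chl+", plus_mean, soil, ph, rep, 1, "end", 1)
                emit(f"{soil}_pH{ph:.2f}_r{rep}_chl-", minus_mean, soil, ph, rep, 0, "end", 1)

        # no-nitrate controls at the unperturbed condition
        nn_growth = np.ones(n_asv)
        nn_growth[np.isin(asv_ids, list(nn_responders))] = 20.0
        for rep in range(1, spec.replicates + 1):
            emit(f"{soil}_NN_r{rep}_chl+", t0_mean, soil, native, rep, 1, "end", 0)
            emit(f"{soil}_NN_r{rep}_chl-", t0_mean * nn_growth, soil, native, rep, 0, "end", 0)

    counts = pd.DataFrame(columns, index=asv_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    spike = pd.Series(spikes, name="spike_in")
    table = CountTable(counts=counts, spike_in=spike, taxonomy=taxonomy, meta=meta)
    return table, CountTruth(
        c_frac=c_frac,
        c0=c0,
        spike_asvs=("SPIKE1", "SPIKE2"),
        growers_by_condition=growers,
        nn_responders=nn_responders,
        firmicutes_centers=centers,
        taxonomy=taxonomy,
    )


def make_presence_panel(
    n_soils: int = 10,
    samples_per_soil: int = 4,
    n_taxa: int = 120,
    native_ph_range: Tuple[float, float] = (4.7, 8.3),
    ph_window: float = 0.8,
    base_rate: float = 0.05,
    peak_rate: float = 0.9,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary presence matrix with a pH-ordered taxon pool.

    Each taxon has a preferred pH; in a given sample it is present with
    probability ``peak_rate`` * exp(-(center - native)^2 / (2 ph_window^2))
    + ``base_rate`` — a soft pH niche rather than a hard window, so
    presence varies between replicate samples of the same soil the way
    detection varies with sampling depth.  Returns (X, y, soil_ids) with
    one native pH per soil, the planted predictive structure used to
    exercise the sparse-regression pipeline.
    """
    rng = np.random.default_rng(seed)
    lo, hi = native_ph_range
    native = np.linspace(lo, hi, n_soils)
    centers = rng.uniform(lo - 0.3, hi + 0.3, size=n_taxa)
    rows, y, soils = [], [], []
    for i in range(n_soils):
        prob = np.clip(
            peak_rate * np.exp(-((centers - native[i]) ** 2) / (2 * ph_window**2))
            + base_rate,
            0.0,
            1.0,
        )
        for _ in range(samples_per_soil):
            rows.append((rng.random(n_taxa) < prob).astype(float))
            y.append(native[i])
            soils.append(f"S{i + 1:02d}")
    return np.array(rows), np.array(y), np.array(soils)
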