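"""Seeded generators for synthetic study inputs.

Three generators emulate the data the analyses consume:

* :func:`gen_metabolome` — a carbon-source × timepoint × replicate GC–MS
  intensity table (default: 2 × 2 × 6, ~81 metabolites) with multiplicative
  lognormal noise, per-sample injection factors, spiked internal standards,
  and fold-change effects planted on the log2 scale so ground truth is exact
  by construction.
* :func:`gen_timecourse` — fermentation records with logistic biomass
  growth, Luedeking–Piret product formation (growth-associated α,
  non-growth-associated β) and yield-coupled substrate draw-down.
* :func:`gen_toy_networks` — small random carbon-balanced metabolic
  networks, fodder for cross-checking the LP solver against brute force.

Each generator derives its random stream as ``SeedSequence([seed, GEN_ID])``
with a fixed per-generator id, so adding generators never perturbs existing
outputs for the same user seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fermentation import FermentationRecord
from .metabolomics import IntensityTable
from .model_core import MetabolicModel, Metabolite, Reaction

__all__ = [
    "MetabolomeSpec",
    "TimecourseSpec",
    "gen_metabolome",
    "gen_timecourse",
    "gen_toy_networks",
]

_GEN_ID_METABOLOME = 1
_GEN_ID_TIMECOURSE = 2
_GEN_ID_NETWORKS = 3


def _rng(seed: int, gen_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), gen_id]))


# ---------------------------------------------------------------------------
# metabolome


@dataclass
class MetabolomeSpec:
    """Design of a synthetic metabolome table.

    ``planted_effects`` maps ``(metabolite_id, group)`` to a log2 shift of
    that metabolite's mean in that group relative to the reference group
    (the first in ``groups``).  ``sigma_log`` is the replicate noise sd on
    the natural-log scale; ``injection_sigma_log`` the per-sample injection
    factor sd (set 0 to disable); explicit ``injection_factors`` override
    the random draw.
    """

    n_metabolites: int = 81
    groups: tuple[tuple[str, int], ...] = (
        ("glucose", 48),
        ("glucose", 72),
        ("sucrose", 48),
        ("sucrose", 72),
    )
    n_replicates: int = 6
    baseline_log_mean: float = 12.0
    baseline_log_sd: float = 1.5
    sigma_log: float = 0.5
    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    injection_sigma_log: float = 0.2
    injection_factors: tuple[float, ...] | None = None
    n_internal_standards: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be positive")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.sigma_log < 0 or self.injection_sigma_log < 0:
            raise ValueError("noise sigmas must be non-negative")
        if not all(map(math.isfinite, self.planted_effects.values())):
            raise ValueError("planted effects must be finite")
        if self.n_internal_standards < 0:
            raise ValueError("n_internal_standards must be non-negative")

    def group_names(self) -> list[str]:
        return [f"{cs}_{tp}" for cs, tp in self.groups]

    def metabolite_ids(self) -> list[str]:
        return [f"M{i+1:03d}" for i in range(self.n_metabolites)]

    def standard_ids(self) -> list[str]:
        return [f"IS{i+1}" for i in range(self.n_internal_standards)]

    def n_samples(self) -> int:
        return len(self.groups) * self.n_replicates

    def with_planted(
        self, n_affected: int, effect_log2: float, groups: tuple[str, ...] | None = None
    ) -> "MetabolomeSpec":
        """Copy of this spec with ``effect_log2`` planted (alternating sign)
        on the first ``n_affected`` metabolites in the given groups (default:
        every non-reference group)."""
        targets = groups if groups is not None else tuple(self.group_names()[1:])
        effects = dict(self.planted_effects)
        for i, mid in enumerate(self.metabolite_ids()[:n_affected]):
            signed = effect_log2 if i % 2 == 0 else -effect_log2
            for g in targets:
                effects[(mid, g)] = signed
        out = MetabolomeSpec(**{**self.__dict__, "planted_effects": effects})
        return out


def gen_metabolome(spec: MetabolomeSpec) -> tuple[IntensityTable, pd.DataFrame]:
    """Generate an intensity table and the truth table of planted effects.

    Intensity of metabolite *i* in sample *s* of group *g*::

        exp( Normal(baseline_i + effect_{i,g}·ln2, sigma_log) ) · injection_s

    Internal-standard rows are constant across samples up to the injection
    factor.  Identical spec (including seed) → identical output.
    """
    spec.validate()
    rng = _rng(spec.seed, _GEN_ID_METABOLOME)
    met_ids = spec.metabolite_ids()
    group_names = spec.group_names()
    sample_ids, design_rows = [], []
    for (cs, tp), gname in zip(spec.groups, group_names):
        for rep in range(1, spec.n_replicates + 1):
            sample_ids.append(f"{gname}_r{rep}")
            design_rows.append({"carbon_source": cs, "timepoint_h": tp,
                                "replicate": rep})
    design = pd.DataFrame(design_rows, index=sample_ids)

    baselines = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd,
                           size=spec.n_metabolites)
    if spec.injection_factors is not None:
        injection = np.asarray(spec.injection_factors, dtype=float)
        if injection.shape != (len(sample_ids),):
            raise ValueError(
                f"injection_factors must have length {len(sample_ids)}"
            )
        if (injection <= 0).any():
            raise ValueError("injection factors must be positive")
    elif spec.injection_sigma_log > 0:
        injection = np.exp(rng.normal(0.0, spec.injection_sigma_log,
                                      size=len(sample_ids)))
    else:
        injection = np.ones(len(sample_ids))

    log_means = np.tile(baselines[:, None], (1, len(sample_ids)))
    for (mid, gname), eff in spec.planted_effects.items():
        if mid not in met_ids:
            raise ValueError(f"planted effect on unknown metabolite {mid!r}")
        if gname not in group_names:
            raise ValueError(f"planted effect on unknown group {gname!r}")
        i = met_ids.index(mid)
        for s, sid in enumerate(sample_ids):
            if sid.rsplit("_r", 1)[0] == gname:
                log_means[i, s] += eff * math.log(2)

    noise = rng.normal(0.0, spec.sigma_log, size=log_means.shape) \
        if spec.sigma_log > 0 else 0.0
    values = np.exp(log_means + noise) * injection[None, :]

    standard_rows = {
        sid: 10 ** (5 + k) * injection
        for k, sid in enumerate(spec.standard_ids())
    }
    frame = pd.DataFrame(values, index=met_ids, columns=sample_ids)
    for sid, row in standard_rows.items():
        frame.loc[sid] = row

    truth = pd.DataFrame(
        [
            {"metabolite": mid, "group": gname, "log2_effect": eff}
            for (mid, gname), eff in sorted(spec.planted_effects.items())
        ],
        columns=["metabolite", "group", "log2_effect"],
    )
    table = IntensityTable(
        values=frame,
        design=design,
        internal_standard_ids=tuple(spec.standard_ids()),
    )
    return table, truth


# ---------------------------------------------------------------------------
# fermentation time course


@dataclass
class TimecourseSpec:
    """Logistic growth + Luedeking–Piret product formation.

    Biomass follows X(t) = Xmax / (1 + ((Xmax−X0)/X0)·exp(−μt)); product
    integrates dP/dt = α·dX/dt + β·X; substrate decreases by P/yield_product
    plus (X−X0)/yield_biomass (skip the biomass draw when ``yield_biomass``
    is None).  Product is reported as malic-acid equivalent in ``ma_g_L`` and
    as polymer in ``pma_g_L`` via ``residue_factor``.
    """

    x0_g_L: float = 0.5
    xmax_g_L: float = 20.0
    mu_per_h: float = 0.15
    alpha_g_g: float = 0.3
    beta_g_g_h: float = 0.025
    yield_product_g_g: float = 0.62
    yield_biomass_g_g: float | None = 0.5
    substrate0_g_L: float = 95.0
    substrate: str = "sucrose"
    sampling_times_h: tuple[float, ...] = tuple(float(t) for t in range(0, 66, 6))
    noise_sd: float = 0.0
    residue_factor: float = 0.8656497704965545
    seed: int = 0

    def validate(self) -> None:
        if not (self.xmax_g_L > self.x0_g_L > 0):
            raise ValueError("need Xmax > X0 > 0")
        if self.mu_per_h <= 0:
            raise ValueError("mu must be positive")
        if self.yield_product_g_g <= 0:
            raise ValueError("product yield must be positive")
        if self.yield_biomass_g_g is not None and self.yield_biomass_g_g <= 0:
            raise ValueError("biomass yield must be positive")
        times = self.sampling_times_h
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])) or not times:
            raise ValueError("sampling times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def _logistic_x(spec: TimecourseSpec, t: np.ndarray) -> np.ndarray:
    a = (spec.xmax_g_L - spec.x0_g_L) / spec.x0_g_L
    return spec.xmax_g_L / (1 + a * np.exp(-spec.mu_per_h * t))


def _logistic_integral(spec: TimecourseSpec, t: np.ndarray) -> np.ndarray:
    # closed form of ∫0^t X dτ for the logistic solution
    a = (spec.xmax_g_L - spec.x0_g_L) / spec.x0_g_L
    return (spec.xmax_g_L / spec.mu_per_h) * np.log(
        (1 + a * np.exp(-spec.mu_per_h * t)) / (1 + a)
    ) + spec.xmax_g_L * t


def gen_timecourse(spec: TimecourseSpec) -> list[FermentationRecord]:
    """Generate fermentation records from the closed-form kinetics, with
    optional additive observation noise (truncated at 0)."""
    spec.validate()
    rng = _rng(spec.seed, _GEN_ID_TIMECOURSE)
    t = np.asarray(spec.sampling_times_h, dtype=float)
    x = _logistic_x(spec, t)
    ma = spec.alpha_g_g * (x - spec.x0_g_L) + spec.beta_g_g_h * _logistic_integral(spec, t)
    consumed = ma / spec.yield_product_g_g
    if spec.yield_biomass_g_g is not None:
        consumed = consumed + (x - spec.x0_g_L) / spec.yield_biomass_g_g
    substrate = np.clip(spec.substrate0_g_L - consumed, 0.0, None)
    if spec.noise_sd > 0:
        x = np.clip(x + rng.normal(0, spec.noise_sd, t.shape), 0, None)
        ma = np.clip(ma + rng.normal(0, spec.noise_sd, t.shape), 0, None)
        substrate = np.clip(substrate + rng.normal(0, spec.noise_sd, t.shape), 0, None)
    records = []
    for ti, xi, mi, si in zip(t, x, ma, substrate):
        sugars = {"sucrose_g_L": 0.0, "glucose_g_L": 0.0, "fructose_g_L": 0.0}
        sugars[f"{spec.substrate}_g_L"] = float(si)
        records.append(
            FermentationRecord(
                time_h=float(ti),
                biomass_g_L=float(xi),
                pma_g_L=float(mi * spec.residue_factor),
                ma_g_L=float(mi),
                sugars_g_L=sugars,
            )
        )
    return records


# ---------------------------------------------------------------------------
# toy networks


def gen_toy_networks(
    seed: int, n_networks: int, max_reactions: int = 8
) -> list[MetabolicModel]:
    """Random small carbon-balanced networks: one uptake exchange, one
    secretion exchange, random internal conversions/splits, finite bounds,
    always feasible (zero flux is inside every box)."""
    if max_reactions > 8:
        raise ValueError("toy networks are limited to 8 reactions")
    if max_reactions < 3:
        raise ValueError("need at least uptake, one conversion, secretion")
    rng = _rng(seed, _GEN_ID_NETWORKS)
    models = []
    for k in range(n_networks):
        n_mets = int(rng.integers(2, min(4, max_reactions - 1) + 1))
        carbons = rng.integers(1, 7, size=n_mets)
        mets = [
            Metabolite(f"m{i}", f"species {i}", "cytosol",
                       {"C": int(carbons[i]), "H": 2 * int(carbons[i]), "O": 1})
            for i in range(n_mets)
        ]
        reactions = [
            Reaction("EX_in", "uptake", {"m0": -1.0},
                     -float(rng.integers(1, 20)), 0.0, "exchange"),
            Reaction("EX_out", "secretion", {f"m{n_mets-1}": -1.0},
                     0.0, float(rng.integers(5, 40)), "exchange"),
        ]
        # a guaranteed chain m0 -> m1 -> ... keeps the optimum nonzero,
        # then random extra conversions up to the reaction budget
        pairs = [(i, i + 1) for i in range(n_mets - 1)]
        n_extra = int(rng.integers(0, max(0, max_reactions - 2 - len(pairs)) + 1))
        for _ in range(n_extra):
            i_src = int(rng.integers(0, n_mets - 1))
            i_dst = int(rng.integers(i_src + 1, n_mets))
            pairs.append((i_src, i_dst))
        for j, (i_src, i_dst) in enumerate(pairs):
            c_src, c_dst = int(carbons[i_src]), int(carbons[i_dst])
            g = math.gcd(c_src, c_dst)
            stoich = {f"m{i_src}": -float(c_dst // g), f"m{i_dst}": float(c_src // g)}
            reversible = bool(rng.random() < 0.3)
            ub = float(rng.integers(2, 30))
            reactions.append(
                Reaction(f"R{j}", f"conversion {i_src}->{i_dst}", stoich,
                         -ub if reversible else 0.0, ub, "internal")
            )
        model = MetabolicModel(
            metabolites=mets, reactions=reactions, objective_id="EX_out",
            notes=[f"toy network {k}"],
        )
        model.validate()
        models.append(model)
    return models
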