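"""Synthetic protein families and assay data with planted ground truth.

The family generator emulates the statistical structure of a two-domain
p-loop ATPase family (Kti12/PSTK-like): a conserved N-terminal ATPase domain
carrying a Walker A motif whose signature residue sits at position 14, a
conserved C-terminal tRNA-binding domain, and an interdomain linker whose
length and composition differ between sequence classes.  Three linker
populations are emulated by default: an animal-type 18-22 residue class, a
plant/yeast-type ~30 residue class, and an elongated 55-60 residue class
whose members carry L (or I) instead of the canonical p-loop lysine.

The alignment is built by construction rather than by running an aligner:
domain columns are shared across sequences and linkers are right-aligned
against the CTD with gap padding, so the planted co-segregating column index
is exact and every downstream stage can be tested against known truth.

Assay simulators produce one-site binding titrations, Boltzmann melt traces,
and malachite-green-style ATPase endpoints from known parameters, so that the
fitting routines can be checked for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import ATPaseMeasurement, BindingCurve, MeltCurve
from .errors import ConfigurationError
from .family import AMINO_ACIDS, GAP, AlignedFamily

__all__ = [
    "ClassSpec",
    "FamilyConfig",
    "PlantedTruth",
    "BindingCurveSim",
    "MeltCurveSim",
    "generate_family",
    "generate_binding_curve",
    "generate_melt_curve",
    "generate_atpase_endpoints",
    "two_class_config",
    "three_population_config",
    "BACKGROUND_COMPOSITION",
]

_AA = np.array(list(AMINO_ACIDS), dtype="U1")

# average globular-protein residue frequencies, normalised at import
_BG = np.array([
    0.083, 0.014, 0.054, 0.067, 0.039, 0.071, 0.023, 0.059, 0.058, 0.097,
    0.024, 0.040, 0.047, 0.039, 0.055, 0.066, 0.053, 0.068, 0.011, 0.029,
])
BACKGROUND_COMPOSITION = _BG / _BG.sum()

# Walker A motif [AG]-x(4)-G-K-[ST]: template residues at 1-based positions
# 8 (G), 13 (G), 15 (T); the variable signature position is 14.
PLOOP_POSITION = 14
_MOTIF_FIXED = {8: "G", 13: "G", 15: "T"}
_ELONGATED_SYMBOLS = frozenset("LI")


def _long_linker_composition() -> np.ndarray:
    """Background composition with Thr doubled and Lys halved, renormalised."""
    comp = BACKGROUND_COMPOSITION.copy()
    comp[AMINO_ACIDS.index("T")] *= 2.0
    comp[AMINO_ACIDS.index("K")] *= 0.5
    return comp / comp.sum()


@dataclass(frozen=True)
class ClassSpec:
    """One linker class: name, length range, p-loop symbol, coupling."""

    name: str
    linker_range: tuple[int, int]
    ploop_symbol: str
    coupling_prob: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.linker_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"bad linker range {self.linker_range}")
        if self.ploop_symbol not in {"K", "L", "I"}:
            raise ConfigurationError(f"p-loop symbol must be K, L or I, got {self.ploop_symbol!r}")
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ConfigurationError("coupling_prob must be in [0, 1]")

    @property
    def elongated(self) -> bool:
        """Super-class membership: L/I-carrying classes are the elongated type."""
        return self.ploop_symbol in _ELONGATED_SYMBOLS


@dataclass
class FamilyConfig:
    """Configuration of a planted-truth family simulation.

    ``mutation_rate`` is the per-site substitution probability of each
    sequence against its class consensus; ``class_divergence`` resamples that
    fraction of non-motif consensus sites independently per class, giving the
    classes distinct consensus backbones (used for phylogenetic clustering
    tests; 0 keeps a single shared backbone so that only the planted p-loop
    column separates the classes).
    """

    n_per_class: int = 100
    class_specs: list[ClassSpec] = field(default_factory=lambda: [
        ClassSpec("regular", (18, 22), "K", 1.0),
        ClassSpec("elongated", (55, 60), "L", 1.0),
    ])
    linker_composition: dict[str, np.ndarray] | None = None
    ntd_length: int = 120
    ctd_length: int = 80
    mutation_rate: float = 0.05
    class_divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        if self.ntd_length < 20:
            raise ConfigurationError("ntd_length must be >= 20 (p-loop sits at residue 14)")
        if self.ctd_length < 1:
            raise ConfigurationError("ctd_length must be >= 1")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ConfigurationError("mutation_rate must be in [0, 1)")
        if not 0.0 <= self.class_divergence <= 1.0:
            raise ConfigurationError("class_divergence must be in [0, 1]")
        if len({s.name for s in self.class_specs}) != len(self.class_specs):
            raise ConfigurationError("class names must be unique")
        if not self.class_specs:
            raise ConfigurationError("need at least one class spec")
        self._check_super_class_ranges()
        self._resolve_compositions()

    def _check_super_class_ranges(self) -> None:
        if any(s.coupling_prob < 1.0 for s in self.class_specs):
            return
        reg = [s.linker_range for s in self.class_specs if not s.elongated]
        elo = [s.linker_range for s in self.class_specs if s.elongated]
        for rlo, rhi in reg:
            for elo_lo, elo_hi in elo:
                if rlo <= elo_hi and elo_lo <= rhi:
                    raise ConfigurationError(
                        "regular and elongated linker ranges overlap with coupling_prob=1"
                    )

    def _resolve_compositions(self) -> None:
        comps: dict[str, np.ndarray] = {}
        given = self.linker_composition or {}
        for spec in self.class_specs:
            if spec.name in given:
                v = np.asarray(given[spec.name], dtype=float)
                if v.shape != (20,):
                    raise ConfigurationError("composition vectors must have 20 entries")
                if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"composition for {spec.name!r} must be non-negative and sum to 1"
                    )
                comps[spec.name] = v
            else:
                comps[spec.name] = (
                    _long_linker_composition() if spec.elongated
                    else BACKGROUND_COMPOSITION.copy()
                )
        self.linker_composition = comps


@dataclass
class PlantedTruth:
    """Ground truth of a generated family, for recovery tests."""

    labels: dict[str, str]
    planted_column: int  # 1-based alignment column of the p-loop
    ploop_symbols: dict[str, str]
    linker_lengths: dict[str, int]
    ntd_length: int
    linker_width: int  # gap-padded width of the linker block

    @property
    def ref_ntd_end(self) -> int:
        """Last NTD residue (reference boundary usable with partition_domains)."""
        return self.ntd_length

    def ref_ctd_start(self, seq_id: str) -> int:
        """First CTD residue of ``seq_id`` on its ungapped coordinates."""
        return self.ntd_length + self.linker_lengths[seq_id] + 1

    def write_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "planted_column": self.planted_column,
            "ploop_symbols": self.ploop_symbols,
            "linker_lengths": self.linker_lengths,
            "ntd_length": self.ntd_length,
            "linker_width": self.linker_width,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            protected: set[int]) -> np.ndarray:
    """Substitute each unprotected site with prob ``rate`` (indices 0-based)."""
    out = seq.copy()
    if rate <= 0:
        return out
    mask = rng.random(seq.size) < rate
    for i in protected:
        mask[i] = False
    for i in np.nonzero(mask)[0]:
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_family(config: FamilyConfig) -> tuple[AlignedFamily, PlantedTruth]:
    """Build an aligned family with a planted co-segregating p-loop column.

    Returns the alignment (NTD columns, gap-padded linker block, CTD columns)
    together with the planted truth.  With ``coupling_prob = 1`` in every
    class, the symbol at the planted column separates the classes perfectly.
    """
    rng = np.random.default_rng(config.seed)
    ntd_len, ctd_len = config.ntd_length, config.ctd_length
    width = max(hi for s in config.class_specs for hi in [s.linker_range[1]])

    # family-wide consensus, Walker A template imposed
    ntd_cons = rng.choice(_AA, size=ntd_len)
    for pos, res in _MOTIF_FIXED.items():
        ntd_cons[pos - 1] = res
    ctd_cons = rng.choice(_AA, size=ctd_len)

    motif_idx0 = {pos - 1 for pos in _MOTIF_FIXED} | {PLOOP_POSITION - 1}

    # optional per-class divergence of the consensus backbone
    class_cons: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for spec in config.class_specs:
        cn, cc = ntd_cons.copy(), ctd_cons.copy()
        if config.class_divergence > 0:
            nmask = rng.random(ntd_len) < config.class_divergence
            for i in motif_idx0:
                nmask[i] = False
            for i in np.nonzero(nmask)[0]:
                cn[i] = rng.choice(_AA[_AA != cn[i]])
            cmask = rng.random(ctd_len) < config.class_divergence
            for i in np.nonzero(cmask)[0]:
                cc[i] = rng.choice(_AA[_AA != cc[i]])
        class_cons[spec.name] = (cn, cc)

    other_symbols = {
        spec.name: sorted({s.ploop_symbol for s in config.class_specs} - {spec.ploop_symbol})
        for spec in config.class_specs
    }

    ids: list[str] = []
    seqs: list[str] = []
    labels: dict[str, str] = {}
    symbols: dict[str, str] = {}
    lengths: dict[str, int] = {}
    taxa: list[str] = []
    k_global = 0
    for spec in config.class_specs:
        cn, cc = class_cons[spec.name]
        comp = config.linker_composition[spec.name]
        lo, hi = spec.linker_range
        for k in range(config.n_per_class):
            seq_id = f"{spec.name}_{k:03d}"
            ntd = _mutate(rng, cn, config.mutation_rate, motif_idx0)
            ctd = _mutate(rng, cc, config.mutation_rate, set())
            if spec.coupling_prob >= 1.0 or rng.random() < spec.coupling_prob:
                sym = spec.ploop_symbol
            elif other_symbols[spec.name]:
                sym = other_symbols[spec.name][rng.integers(len(other_symbols[spec.name]))]
            else:
                sym = spec.ploop_symbol
            ntd[PLOOP_POSITION - 1] = sym
            llen = int(rng.integers(lo, hi + 1))
            linker = rng.choice(_AA, size=llen, p=comp)
            aligned = "".join(ntd) + GAP * (width - llen) + "".join(linker) + "".join(ctd)
            ids.append(seq_id)
            seqs.append(aligned)
            labels[seq_id] = spec.name
            symbols[seq_id] = sym
            lengths[seq_id] = llen
            taxa.append(f"sp{k_global:04d}")
            k_global += 1

    meta = pd.DataFrame(
        {"taxon": taxa, "class": [labels[i] for i in ids]},
        index=pd.Index(ids, name="id"),
    )
    family = AlignedFamily(ids=ids, seqs=seqs, meta=meta)
    truth = PlantedTruth(
        labels=labels,
        planted_column=PLOOP_POSITION,  # NTD columns are gapless, column == residue
        ploop_symbols=symbols,
        linker_lengths=lengths,
        ntd_length=ntd_len,
        linker_width=width,
    )
    return family, truth


def two_class_config(n_per_class: int = 100, seed: int = 0, **kw) -> FamilyConfig:
    """Regular (18-22, K14) vs elongated (55-60, L14) two-class family."""
    return FamilyConfig(n_per_class=n_per_class, seed=seed, **kw)


def three_population_config(n_per_class: int = 100, seed: int = 0, **kw) -> FamilyConfig:
    """Animal-type, plant-type, and elongated linker populations."""
    return FamilyConfig(
        n_per_class=n_per_class,
        class_specs=[
            ClassSpec("animal_type", (18, 22), "K", 1.0),
            ClassSpec("plant_type", (28, 32), "K", 1.0),
            ClassSpec("elongated", (55, 60), "L", 1.0),
        ],
        seed=seed,
        **kw,
    )


# ---------------------------------------------------------------------------
# assay simulators
# ---------------------------------------------------------------------------


@dataclass
class BindingCurveSim:
    """Serial two-fold protein dilutions probed at a fixed tracer concentration."""

    true_kd: float
    start_conc: float = 100.0  # uM, highest protein concentration
    n_dilutions: int = 12
    n_replicates: int = 3
    probe_conc: float = 1.0  # uM
    p0: float = 50.0  # baseline polarization
    pmax: float = 200.0  # saturation polarization
    noise_sd: float = 0.02  # fraction of the dynamic range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_kd <= 0 or self.start_conc <= 0:
            raise ConfigurationError("Kd and start concentration must be positive")
        if self.n_dilutions < 2:
            raise ConfigurationError("need at least 2 dilutions")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        return self.start_conc / 2.0 ** np.arange(self.n_dilutions)


def generate_binding_curve(sim: BindingCurveSim) -> BindingCurve:
    """Noisy one-site titration; deterministic under a fixed seed."""
    rng = np.random.default_rng(sim.seed)
    c = np.repeat(sim.concentrations, sim.n_replicates)
    p = sim.p0 + (sim.pmax - sim.p0) * c / (sim.true_kd + c)
    p = p + rng.normal(0.0, sim.noise_sd * (sim.pmax - sim.p0), size=c.size)
    return BindingCurve(concentrations=c, polarization=p)


@dataclass
class MeltCurveSim:
    """Boltzmann unfolding transition on a thermal ramp."""

    true_tm: float
    t_min: float = 4.0
    t_max: float = 98.0
    t_step: float = 0.5  # degC between readings along the ramp
    slope: float = 2.0  # transition width, degC
    f_pre: float = 10.0
    f_post: float = 100.0
    noise_sd: float = 0.01  # fraction of the amplitude
    aggregation: bool = False  # add a post-transition fluorescence decline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_step <= 0 or self.t_min >= self.t_max:
            raise ConfigurationError("temperature grid must be increasing")
        if not self.t_min <= self.true_tm <= self.t_max:
            raise ConfigurationError("true_tm must lie inside the temperature grid")
        if self.slope < 0 or self.noise_sd < 0:
            raise ConfigurationError("slope and noise_sd must be >= 0")

    @property
    def temperatures(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + 0.5 * self.t_step, self.t_step)


def generate_melt_curve(sim: MeltCurveSim) -> MeltCurve:
    """Noisy melt trace; a zero slope degenerates to a step at Tm."""
    rng = np.random.default_rng(sim.seed)
    t = sim.temperatures
    amp = sim.f_post - sim.f_pre
    if sim.slope == 0.0:
        f = np.where(t < sim.true_tm, sim.f_pre, sim.f_post).astype(float)
    else:
        f = sim.f_pre + amp / (1.0 + np.exp((sim.true_tm - t) / sim.slope))
    if sim.aggregation:
        onset = sim.true_tm + 4.0 * max(sim.slope, 1.0)
        frac = np.clip((t - onset) / max(sim.t_max - onset, 1e-9), 0.0, 1.0)
        f = f - 0.4 * amp * frac
    f = f + rng.normal(0.0, sim.noise_sd * abs(amp), size=t.size)
    return MeltCurve(temperatures=t, fluorescence=f)


def generate_atpase_endpoints(rates: dict[str, float], duration: float,
                              n_reps: int = 3, noise_sd: float = 1.0,
                              seed: int = 0) -> dict[str, ATPaseMeasurement]:
    """Endpoint phosphate readings per variant: ``rate * duration + noise``.

    ``rates`` are Pi-release rates in uM/h, ``duration`` in hours,
    ``noise_sd`` the absolute endpoint standard deviation in uM.
    """
    if any(r < 0 for r in rates.values()):
        raise ConfigurationError("rates must be >= 0")
    if n_reps < 2:
        raise ConfigurationError("need n_reps >= 2")
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for variant, rate in rates.items():
        vals = rate * duration + rng.normal(0.0, noise_sd, size=n_reps)
        out[variant] = ATPaseMeasurement(variant=variant, endpoints=vals)
    return out


def atpase_to_frame(measurements: dict[str, ATPaseMeasurement]) -> pd.DataFrame:
    """Long-format table (variant, replicate, endpoint_um) for CSV export."""
    rows = [
        {"variant": v, "replicate": k + 1, "endpoint_um": float(x)}
        for v, m in measurements.items()
        for k, x in enumerate(m.endpoints)
    ]
    return pd.DataFrame(rows)
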