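"""Synthetic ground-truth cohorts and instrument-facing inputs.

The generator emulates what a targeted LC/MS run on tumor interstitial fluid
(TIF) and plasma produces, from known ground truth:

* true metabolite concentrations per sample, lognormal across metabolites with
  group effects on a log2 scale and lognormal biological variation;
* a per-sample multiplicative **matrix factor** shared by every species in
  that sample — the ion suppression/enhancement that makes isotope dilution
  matrix-robust and external calibration only semi-quantitative;
* per-metabolite response factors (area units per µM), equal for the labeled
  and unlabeled forms of a metabolite;
* multiplicative lognormal instrument noise with a stated CV;
* detection censoring: a species whose noiseless area falls below the floor
  implied by its true LOD is emitted as missing.

The observation model for the unlabeled analyte m in sample s is::

    area(s, m) = rf(m) * conc(s, m) * matrix(s) * eps,   eps ~ logN(CV)

and for a labeled standard j (spiked identically into every sample through
the extraction mix)::

    area(s, j) = rf(j) * is_conc(j) * matrix(s, j) * eps,

where matrix(s, j) is the sample's co-elution matrix factor: a labeled twin
co-elutes exactly with its analyte and shares matrix(s) (so isotope dilution
cancels it), while a dedicated RT-paired normalizer amino acid elutes only
roughly nearby and draws its own independent per-sample ionization factor —
the reason external calibration stays semi-quantitative even after
normalization.  On top of the per-sample factor, each metabolite has a fixed
per-matrix-class susceptibility (how strongly plasma or TIF suppresses or
enhances it), which produces the wide per-standard spread seen when equal
spikes are compared between water and plasma.

Everything stochastic flows from the single seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import PeakTable, SampleSheet, StandardEntry, StandardsLibrary
from .ldh import KineticTrace

#: the eight external-standard pool stock levels (µM), highest first
DEFAULT_POOL_LEVELS_UM = (5000.0, 1000.0, 300.0, 100.0, 30.0, 10.0, 3.0, 1.0)

#: internal-standard species naming convention
def is_species(metabolite_id: str) -> str:
    return f"13C-{metabolite_id}"


@dataclass(frozen=True)
class GroupSpec:
    """One biological group: label, size, matrix type and log2 effect sizes.

    ``log2_effects`` is either a scalar applied to a random subset (see
    ``affected_fraction``), a full per-metabolite vector, or 0 for a null
    group.
    """

    label: str
    n_samples: int
    matrix_type: str = "tif"
    log2_effects: float | np.ndarray = 0.0
    affected_fraction: float = 0.0  # used only when log2_effects is a scalar


@dataclass(frozen=True)
class MatrixFactorSpec:
    """Distribution of the per-sample matrix factor for one matrix type."""

    kind: str = "lognormal"  # "lognormal" | "uniform" | "fixed"
    geometric_sd: float = 1.6  # lognormal, median 1
    low: float = 0.3  # uniform bounds
    high: float = 3.0
    value: float = 1.0  # fixed

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.value)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.kind == "lognormal":
            return rng.lognormal(mean=0.0, sigma=np.log(self.geometric_sd), size=n)
        raise ConfigError(f"unknown matrix-factor kind {self.kind!r}")


@dataclass(frozen=True)
class GroundTruthConfig:
    """Parameters of the simulated study.

    Defaults mirror the real assay: a 149-metabolite library split over seven
    pools with eight stock levels from ~5 mM down to ~1 µM, 70 metabolites on
    the stable-isotope-dilution path, per-metabolite LODs between 0.1 and
    3 µM, plasma/TIF matrix factors spanning both suppression and enhancement
    (lognormal, geometric SD 1.6), and 5% multiplicative instrument noise.
    """

    n_metabolites: int = 149
    fraction_isotope_dilution: float = 70 / 149
    n_pools: int = 7
    pool_levels_um: tuple[float, ...] = DEFAULT_POOL_LEVELS_UM
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("tif", 7, matrix_type="tif"),
        GroupSpec("plasma", 18, matrix_type="plasma"),
    )
    baseline_median_um: float = 20.0
    baseline_gsd: float = 4.0  # across metabolites
    biological_gsd: float = 1.3  # across samples within a group
    matrix_factors: dict[str, MatrixFactorSpec] = field(
        default_factory=lambda: {
            "water": MatrixFactorSpec(kind="fixed", value=1.0),
            "standard_dilution": MatrixFactorSpec(kind="fixed", value=1.0),
            "plasma": MatrixFactorSpec(kind="lognormal", geometric_sd=1.6),
            "tif": MatrixFactorSpec(kind="lognormal", geometric_sd=1.6),
        }
    )
    #: per-metabolite ion-suppression/enhancement spread in biological
    #: matrices (geometric SD of a lognormal factor, 1.0 disables it); shared
    #: by the labeled and unlabeled form of a metabolite, constant across
    #: samples of one matrix class
    susceptibility_gsd: float = 1.6
    #: how much of the sample's log-ionization variation an RT-paired
    #: normalizer shares with the analytes (1 = co-elutes exactly and the
    #: matrix factor cancels under normalization; 0 = fully independent).
    #: The paper-style pairing is only approximate, hence the 0.5 default.
    rt_pairing_fidelity: float = 0.5
    instrument_noise_cv: float = 0.05
    response_factor_median: float = 1e5  # area units per µM
    response_factor_gsd: float = 3.0
    is_conc_median_um: float = 40.0
    is_conc_gsd: float = 1.8
    lod_range_um: tuple[float, float] = (0.1, 3.0)
    n_normalizers: int = 17  # RT-paired labeled amino acids (one standard mix)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_metabolites": self.n_metabolites,
            "n_pools": self.n_pools,
            "baseline_median_um": self.baseline_median_um,
            "baseline_gsd": self.baseline_gsd,
            "biological_gsd": self.biological_gsd,
            "response_factor_median": self.response_factor_median,
            "is_conc_median_um": self.is_conc_median_um,
            "n_normalizers": self.n_normalizers,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.instrument_noise_cv < 0:
            raise ConfigError("instrument_noise_cv must be >= 0")
        if self.susceptibility_gsd < 1.0:
            raise ConfigError("susceptibility_gsd must be >= 1 (geometric SD)")
        if not 0.0 <= self.rt_pairing_fidelity <= 1.0:
            raise ConfigError("rt_pairing_fidelity must be in [0, 1]")
        if not 0.0 <= self.fraction_isotope_dilution <= 1.0:
            raise ConfigError("fraction_isotope_dilution must be in [0, 1]")
        if any(b >= a for a, b in zip(self.pool_levels_um, self.pool_levels_um[1:])):
            raise ConfigError("pool levels must be strictly decreasing")
        if not (self.lod_range_um[0] > 0 and self.lod_range_um[1] >= self.lod_range_um[0]):
            raise ConfigError("lod_range_um must be positive and ordered")
        for g in self.groups:
            if g.n_samples <= 0:
                raise ConfigError(f"group {g.label!r}: n_samples must be positive")
            if not 0.0 <= g.affected_fraction <= 1.0:
                raise ConfigError(f"group {g.label!r}: affected_fraction in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    concentrations: pd.DataFrame  # samples x metabolites, µM
    matrix_factors: pd.Series  # per sample
    is_concentrations: pd.Series  # per labeled standard species, µM
    response_factors: pd.Series  # per metabolite (labeled form shares it)
    lod_true: pd.Series  # per metabolite, µM
    group_labels: pd.Series  # per sample
    susceptibility: pd.DataFrame | None = None  # metabolites x matrix types
    seed: int = 0


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


class SyntheticStudy:
    """A reproducible simulated study: library, truth, and every injection type.

    All random draws derive from ``config.seed`` through named spawn keys, so
    the library, the cohort, the dilution series and the matrix-effect
    injections are mutually consistent and byte-reproducible.
    """

    def __init__(self, config: GroundTruthConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        keys = ("library", "cohort", "dilutions", "matrix_effect", "ldh")
        self._rngs = {
            k: np.random.default_rng(child)
            for k, child in zip(keys, ss.spawn(len(keys)))
        }
        self.library, self._truth_params = self._build_library()

    # -- library and metabolite-level truth ---------------------------------

    def _build_library(self) -> tuple[StandardsLibrary, dict]:
        cfg = self.config
        rng = self._rngs["library"]
        n = cfg.n_metabolites
        met_ids = [f"met{i:03d}" for i in range(n)]
        n_id = int(round(cfg.fraction_isotope_dilution * n))
        modes = np.array(
            ["isotope_dilution"] * n_id + ["external_calibration"] * (n - n_id)
        )
        rng.shuffle(modes)
        # The RT-paired normalizers for the external path are dedicated
        # labeled amino acid standards in the extraction mix.  They elute only
        # roughly at the analyte's retention time, so they do NOT share the
        # analyte's co-elution matrix factor (see generate_cohort).
        normalizers = [f"13C-AA{i+1}" for i in range(cfg.n_normalizers)]
        pools = np.array([f"pool{1 + i % cfg.n_pools}" for i in range(n)])
        rng.shuffle(pools)
        level_tags = [f"L{i+1}" for i in range(len(cfg.pool_levels_um))]
        # per-metabolite jitter of the nominal stock around the pool level
        # (each standard is weighed individually -> "~5 mM" etc.)
        jitter = rng.uniform(0.85, 1.15, size=n)
        rf = rng.lognormal(
            np.log(cfg.response_factor_median), np.log(cfg.response_factor_gsd), size=n
        )
        lod = np.exp(
            rng.uniform(np.log(cfg.lod_range_um[0]), np.log(cfg.lod_range_um[1]), size=n)
        )
        baseline = rng.lognormal(
            np.log(cfg.baseline_median_um), np.log(cfg.baseline_gsd), size=n
        )
        rt = rng.uniform(0.5, 20.0, size=n)
        mz = rng.uniform(70.0, 800.0, size=n)
        entries = []
        ext_counter = 0
        for i, m in enumerate(met_ids):
            if modes[i] == "isotope_dilution":
                paired = is_species(m)
            else:
                paired = normalizers[ext_counter % len(normalizers)]
                ext_counter += 1
            entries.append(
                StandardEntry(
                    metabolite_id=m,
                    pool_id=str(pools[i]),
                    nominal_conc_by_level={
                        tag: float(level * jitter[i])
                        for tag, level in zip(level_tags, cfg.pool_levels_um)
                    },
                    mz=float(mz[i]),
                    retention_time=float(rt[i]),
                    lod=float(lod[i]),
                    quant_mode=str(modes[i]),
                    paired_standard_id=paired,
                )
            )
        library = StandardsLibrary(entries)
        used_normalizers = sorted(
            {e.paired_standard_id for e in entries if e.paired_standard_id in normalizers}
        )
        is_ids = sorted({e.paired_standard_id for e in entries if e.paired_standard_id})
        is_conc = pd.Series(
            rng.lognormal(np.log(cfg.is_conc_median_um), np.log(cfg.is_conc_gsd), len(is_ids)),
            index=is_ids,
            name="is_conc_um",
        )
        # species-group keys: metabolite ids plus dedicated normalizer species
        keys = met_ids + used_normalizers
        rf_norm = rng.lognormal(
            np.log(cfg.response_factor_median),
            np.log(cfg.response_factor_gsd),
            size=len(used_normalizers),
        )
        rf_all = pd.Series(
            np.concatenate([rf, rf_norm]), index=keys, name="response_factor"
        )
        # metabolite-specific ion suppression/enhancement in biological
        # matrices; the labeled twin shares its metabolite's value, so isotope
        # dilution still cancels it exactly
        s_sigma = np.log(cfg.susceptibility_gsd)

        def susc_draw() -> np.ndarray:
            if s_sigma > 0:
                return rng.lognormal(0.0, s_sigma, size=len(keys))
            return np.ones(len(keys))

        susceptibility = pd.DataFrame(
            {
                "water": np.ones(len(keys)),
                "standard_dilution": np.ones(len(keys)),
                "plasma": susc_draw(),
                "tif": susc_draw(),
            },
            index=keys,
        )
        params = {
            "susceptibility": susceptibility,
            "normalizer_ids": used_normalizers,
            "response_factors": rf_all,
            "lod_true": pd.Series(lod, index=met_ids, name="lod_um"),
            "baseline": pd.Series(baseline, index=met_ids, name="baseline_um"),
            "is_concentrations": is_conc,
            "level_tags": level_tags,
        }
        return library, params

    @property
    def is_concentrations(self) -> pd.Series:
        return self._truth_params["is_concentrations"]

    def _group_key(self, species_id: str) -> str:
        """Species-group key: a labeled twin maps to its metabolite; dedicated
        normalizer standards are their own group."""
        table = self._truth_params["response_factors"].index
        if species_id in table:
            return species_id
        if species_id.startswith("13C-") and species_id[4:] in table:
            return species_id[4:]
        raise KeyError(species_id)

    def _rf_of_species(self, species_id: str) -> float:
        """Labeled and unlabeled forms share the metabolite's response factor."""
        return float(self._truth_params["response_factors"][self._group_key(species_id)])

    # -- biological cohort ---------------------------------------------------

    def generate_cohort(self) -> tuple[GroundTruth, SampleSheet, PeakTable]:
        cfg = self.config
        rng = self._rngs["cohort"]
        met_ids = self.library.metabolite_ids
        n_m = len(met_ids)
        baseline = self._truth_params["baseline"].to_numpy()
        rf = self._truth_params["response_factors"]
        lod_true = self._truth_params["lod_true"]
        is_conc = self.is_concentrations

        rows_sheet, sample_ids, group_labels, matrices = [], [], [], []
        conc_rows = []
        for g in cfg.groups:
            effects = np.asarray(g.log2_effects, dtype=float)
            if effects.ndim == 0:
                vec = np.zeros(n_m)
                if g.affected_fraction > 0 and float(effects) != 0.0:
                    k = int(round(g.affected_fraction * n_m))
                    idx = rng.choice(n_m, size=k, replace=False)
                    signs = rng.choice([-1.0, 1.0], size=k)
                    vec[idx] = float(effects) * signs
                effects = vec
            elif effects.shape != (n_m,):
                raise ConfigError(
                    f"group {g.label!r}: log2_effects must be scalar or length {n_m}"
                )
            for j in range(g.n_samples):
                sid = f"{g.label}_{j+1:02d}"
                sample_ids.append(sid)
                group_labels.append(g.label)
                matrices.append(g.matrix_type)
                bio = (
                    rng.lognormal(0.0, np.log(cfg.biological_gsd), size=n_m)
                    if cfg.biological_gsd > 1
                    else np.ones(n_m)
                )
                conc_rows.append(baseline * 2.0**effects * bio)
                rows_sheet.append(
                    {"sample_id": sid, "matrix_type": g.matrix_type, "group": g.label}
                )
        conc = pd.DataFrame(conc_rows, index=sample_ids, columns=met_ids)
        mf = np.concatenate(
            [
                self._matrix_spec(m).draw(1, rng)
                for m in matrices
            ]
        )
        matrix_factors = pd.Series(mf, index=sample_ids, name="matrix_factor")

        susceptibility = self._truth_params["susceptibility"]
        records: list[tuple[str, str, float]] = []
        rf_mets = rf.loc[met_ids].to_numpy()
        for si, sid in enumerate(sample_ids):
            f = mf[si]
            susc = susceptibility.loc[met_ids, matrices[si]].to_numpy()
            # unlabeled analytes
            noiseless = conc.iloc[si].to_numpy() * rf_mets * f * susc
            eps = _noise(rng, cfg.instrument_noise_cv, n_m)
            censored = conc.iloc[si].to_numpy() * f * susc < lod_true.to_numpy()
            for mi, m in enumerate(met_ids):
                area = np.nan if censored[mi] else noiseless[mi] * eps[mi]
                records.append((sid, m, area))
            # labeled standards, spiked identically via the extraction mix.
            # A labeled twin co-elutes with its analyte and shares the
            # sample's matrix factor and susceptibility (isotope dilution
            # cancels both); a dedicated normalizer amino acid elutes only
            # roughly nearby and experiences its own per-sample ionization
            # factor, drawn independently from the same matrix distribution —
            # this is what leaves external calibration semi-quantitative.
            normalizer_ids = set(self._truth_params["normalizer_ids"])
            eps_l = _noise(rng, cfg.instrument_noise_cv, len(is_conc))
            for k, (std_id, c_is) in enumerate(is_conc.items()):
                key = self._group_key(std_id)
                s = susceptibility.loc[key, matrices[si]]
                if std_id in normalizer_ids:
                    # partial sharing: the normalizer sees the sample factor
                    # raised to the pairing fidelity, times an independent
                    # residual from the same matrix distribution
                    w = cfg.rt_pairing_fidelity
                    own = float(self._matrix_spec(matrices[si]).draw(1, rng)[0])
                    f_std = f**w * own ** (1.0 - w)
                else:
                    f_std = f
                area = self._rf_of_species(std_id) * c_is * f_std * s * eps_l[k]
                records.append((sid, std_id, area))

        sheet = SampleSheet(pd.DataFrame(rows_sheet))
        peaks = PeakTable(
            pd.DataFrame(records, columns=["sample_id", "species_id", "peak_area"])
        )
        truth = GroundTruth(
            concentrations=conc,
            matrix_factors=matrix_factors,
            susceptibility=susceptibility.copy(),
            is_concentrations=is_conc.copy(),
            response_factors=rf.copy(),
            lod_true=lod_true.copy(),
            group_labels=pd.Series(group_labels, index=sample_ids, name="group"),
            seed=cfg.seed,
        )
        return truth, sheet, peaks

    def _matrix_spec(self, matrix_type: str) -> MatrixFactorSpec:
        try:
            return self.config.matrix_factors[matrix_type]
        except KeyError:
            raise ConfigError(f"no matrix-factor spec for matrix type {matrix_type!r}")

    # -- external-standard pool dilution series ------------------------------

    def generate_standard_dilutions(self) -> tuple[PeakTable, SampleSheet]:
        """One injection per (pool, dilution level), in water (matrix factor 1).

        The unlabeled area of each pool member tracks its nominal level
        concentration; the labeled internal standards are spiked identically
        into every injection.  Levels whose nominal concentration falls below
        the metabolite's true LOD are censored to missing.
        """
        cfg = self.config
        rng = self._rngs["dilutions"]
        lod_true = self._truth_params["lod_true"]
        is_conc = self.is_concentrations
        records: list[tuple[str, str, float]] = []
        sheet_rows = []
        for pool in self.library.pool_ids:
            members = self.library.pool_members(pool)
            for level in self._truth_params["level_tags"]:
                sid = f"std_{pool}_{level}"
                sheet_rows.append(
                    {
                        "sample_id": sid,
                        "matrix_type": "standard_dilution",
                        "group": "standard",
                        "dilution_level": level,
                        "pool_id": pool,
                    }
                )
                for e in members:
                    if level not in e.nominal_conc_by_level:
                        raise ConfigError(
                            f"{e.metabolite_id}: missing dilution level {level!r}"
                        )
                    nominal = e.nominal_conc_by_level[level]
                    if nominal < lod_true[e.metabolite_id]:
                        records.append((sid, e.metabolite_id, np.nan))
                        continue
                    area = (
                        self._rf_of_species(e.metabolite_id)
                        * nominal
                        * float(_noise(rng, cfg.instrument_noise_cv, 1)[0])
                    )
                    records.append((sid, e.metabolite_id, area))
                for std_id, c_is in is_conc.items():
                    area = (
                        self._rf_of_species(std_id)
                        * c_is
                        * float(_noise(rng, cfg.instrument_noise_cv, 1)[0])
                    )
                    records.append((sid, std_id, area))
        peaks = PeakTable(
            pd.DataFrame(records, columns=["sample_id", "species_id", "peak_area"])
        )
        return peaks, SampleSheet(pd.DataFrame(sheet_rows))

    # -- matrix-effect injections (labeled standards in water vs plasma) -----

    def generate_matrix_effect_injections(
        self, n_water: int = 6, n_plasma: int = 19
    ) -> tuple[PeakTable, PeakTable]:
        """Equal spikes of every labeled standard into water and into plasma."""
        cfg = self.config
        rng = self._rngs["matrix_effect"]
        is_conc = self.is_concentrations

        susceptibility = self._truth_params["susceptibility"]

        def injections(prefix: str, n: int, matrix_type: str) -> PeakTable:
            records = []
            mf = self._matrix_spec(matrix_type).draw(n, rng)
            susc = susceptibility[matrix_type]
            for i in range(n):
                sid = f"{prefix}_{i+1:02d}"
                eps = _noise(rng, cfg.instrument_noise_cv, len(is_conc))
                for k, (std_id, c_is) in enumerate(is_conc.items()):
                    factor = mf[i] * susc[self._group_key(std_id)]
                    records.append(
                        (sid, std_id, self._rf_of_species(std_id) * c_is * factor * eps[k])
                    )
            return PeakTable(
                pd.DataFrame(records, columns=["sample_id", "species_id", "peak_area"])
            )

        water = injections("water", n_water, "water")
        plasma = injections("plasmaMX", n_plasma, "plasma")
        return water, plasma

    # -- LDH kinetic traces ---------------------------------------------------

    def generate_ldh_traces(
        self,
        activities: list[float],
        gain: float = 4.0,
        a0: float = 1.1,
        duration_min: float = 5.0,
        n_points: int = 61,
        noise: float = 0.0,
    ) -> list[KineticTrace]:
        """NADH A340 consumption traces, one per activity (units).

        A340(t) = a0 - gain * activity * t (t in minutes); ``noise`` is the
        SD of additive Gaussian read noise expressed as a fraction of the
        trace's total absorbance span, so relative slope uncertainty is the
        same at every activity.  Zero activity yields a flat, noiseless-span
        trace (the blank has no signal to scale noise by).
        """
        if any(a < 0 for a in activities):
            raise ConfigError("LDH activities must be >= 0")
        if n_points < 5:
            raise ConfigError("traces need at least 5 points")
        rng = self._rngs["ldh"]
        times_min = np.linspace(0.0, duration_min, n_points)
        traces = []
        for a in activities:
            span = gain * a * duration_min
            a340 = a0 - gain * a * times_min
            if noise > 0 and span > 0:
                a340 = a340 + rng.normal(0.0, noise * span, size=n_points)
            traces.append(KineticTrace(times=times_min * 60.0, a340=a340))
        return traces


# -- spec-surface convenience wrappers ---------------------------------------

def generate_cohort(config: GroundTruthConfig) -> tuple[GroundTruth, SampleSheet, PeakTable]:
    return SyntheticStudy(config).generate_cohort()


def generate_standard_dilutions(
    library: StandardsLibrary, config: GroundTruthConfig
) -> tuple[PeakTable, SampleSheet]:
    study = SyntheticStudy(config)
    mine = study.library
    same = set(library.metabolite_ids) == set(mine.metabolite_ids) and all(
        (e := mine[m]).pool_id == library[m].pool_id
        and e.quant_mode == library[m].quant_mode
        and e.nominal_conc_by_level == library[m].nominal_conc_by_level
        for m in mine.metabolite_ids
    )
    if not same:
        raise ConfigError("library does not match the one implied by this config")
    return study.generate_standard_dilutions()


def generate_ldh_traces(
    activities: list[float], config: GroundTruthConfig, **kwargs
) -> list[KineticTrace]:
    return SyntheticStudy(config).generate_ldh_traces(activities, **kwargs)
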