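"""Seeded synthetic-data generators for every analysis stage.

These generators emulate the statistical structure each downstream analysis
assumes, so the whole pipeline can be exercised without any imaging or
sequencing download:

* pulsatile hair-germ volume trajectories at 6-min cadence over 4-6 h, in
  three behavior categories with known truth labels;
* Hertz/Sneddon force-indentation curves on 8x8 grids (64 points per
  15x15 µm region) with flat pre-contact baselines and additive force noise;
* per-cell cortical F-actin / nuclear-YAP pairs with a tunable inverse
  correlation (Gaussian copula) and telogen/anagen stage structure;
* negative-binomial gene x cell count matrices with a population-specific
  actin gene-set fold-change;
* post-ablation recoil traces L(t) = L0 + A(1 - e^(-t/tau)) + noise;
* random 3'UTRs with seed sites planted at known positions.

All randomness flows from the single integer ``seed`` in each parameter
object; identical parameters + seed give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import targets as tg
from .afm import ForceCurve, ForceMap, _geometry_prefactor
from .errors import ParameterError
from .mechano import CellMechRecord
from .recoil import RecoilTrace
from .volume import VolumeTrajectory

# mmu-miR-205-5p mature sequence, used as the default scanner query.
MIR205_SEQUENCE = "UCCUUCAUUCCACCGGAGUCUG"

_NM = 1e-9
_UM = 1e-6
_PN = 1e-12


# --------------------------------------------------------------------------- #
# volume trajectories
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class VolumeSimParams:
    """Hair-germ volume trajectory generator settings.

    Defaults encode a resting-phase (telogen-like) cohort: 31 follicles of
    10-20 cells with per-cell volumes of 454-735 µm³, imaged every 6 min over
    4-6 h, category mix (enlarge, pulsatile, contract) matching the observed
    frequencies, contraction pulses of ~20% depth and 2% CV measurement noise.
    """

    n_follicles: int = 31
    cadence_min: float = 6.0
    duration_h: float = 5.0
    category_mix: tuple[float, float, float] = (0.065, 0.806, 0.129)
    cell_count_range: tuple[int, int] = (10, 20)
    cell_volume_range: tuple[float, float] = (454.0, 735.0)
    pulse_amplitude_pct: float = 20.0
    drift_pct_per_h: float = 5.0
    noise_pct: float = 2.0
    stage: str = "telogen1"
    seed: int = 0

    def validate(self) -> None:
        if not math.isclose(sum(self.category_mix), 1.0, abs_tol=1e-9):
            raise ParameterError("category_mix probabilities must sum to 1")
        if any(p < 0 for p in self.category_mix):
            raise ParameterError("category_mix probabilities must be non-negative")
        if self.cadence_min <= 0:
            raise ParameterError("cadence must be positive")
        if not 4.0 <= self.duration_h <= 6.0:
            raise ParameterError("duration_h must lie in [4, 6] hours")
        for name in ("cell_count_range", "cell_volume_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name}: low must be <= high")
        if self.noise_pct < 0 or self.pulse_amplitude_pct < 0:
            raise ParameterError("noise and pulse amplitude must be non-negative")


# Anagen-like preset: more enlargement, fewer contractions and sub-threshold
# pulses, encoding the observed "reduced contraction" during activation.
ANAGEN_PRESET = dict(
    n_follicles=16,
    category_mix=(0.25, 0.65, 0.10),
    pulse_amplitude_pct=5.0,
    drift_pct_per_h=2.5,
    stage="anagen_early",
)

_CATEGORY_NAMES = ("continuous_enlargement", "pulsatile", "continuous_contraction")


def cohort_point_counts(stage: str) -> list[int]:
    """Per-follicle time-point counts of the packaged cohort layouts.

    The telogen layout has 31 follicles totalling 1,560 points and the early
    anagen layout 16 follicles totalling 655 points (at 6-min cadence these
    correspond to 4-5 h observation windows).
    """
    if stage in ("telogen1", "telogen2"):
        return [50] * 21 + [51] * 10  # 1,560 points
    if stage in ("anagen_early", "induced"):
        return [41] * 15 + [40]  # 655 points
    raise ParameterError(f"unknown stage {stage!r}")


def _raised_cosine(t: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Smooth unit pulse supported on [center - halfwidth, center + halfwidth]."""
    x = (t - center) / halfwidth
    out = np.zeros_like(t)
    mask = np.abs(x) < 1.0
    out[mask] = 0.5 * (1.0 + np.cos(np.pi * x[mask]))
    return out


def gen_volume_trajectories(
    params: VolumeSimParams,
    n_points_per_follicle: list[int] | None = None,
) -> tuple[list[VolumeTrajectory], list[str]]:
    """Generate trajectories plus their true behavior-category labels.

    ``n_points_per_follicle`` overrides the uniform duration (used for the
    packaged cohort layouts); otherwise every follicle runs ``duration_h``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    if n_points_per_follicle is not None and len(n_points_per_follicle) != params.n_follicles:
        raise ParameterError("n_points_per_follicle length must equal n_follicles")

    trajectories: list[VolumeTrajectory] = []
    labels: list[str] = []
    for i in range(params.n_follicles):
        if n_points_per_follicle is None:
            n_pts = int(round(params.duration_h * 60.0 / params.cadence_min)) + 1
        else:
            n_pts = n_points_per_follicle[i]
        t_min = np.arange(n_pts) * params.cadence_min
        t_frac = t_min / t_min[-1]

        category = _CATEGORY_NAMES[rng.choice(3, p=params.category_mix)]
        cells = int(rng.integers(params.cell_count_range[0], params.cell_count_range[1] + 1))
        per_cell = rng.uniform(*params.cell_volume_range)
        base = cells * per_cell

        drift = params.drift_pct_per_h / 100.0 * (t_min / 60.0)
        if category == "continuous_enlargement":
            shape = 1.0 + drift
        elif category == "continuous_contraction":
            shape = 1.0 - drift
        else:  # pulsatile: flat baseline with 1-4 smooth contraction pulses
            shape = np.ones(n_pts)
            n_pulses = int(rng.integers(1, 5))
            for _ in range(n_pulses):
                depth = params.pulse_amplitude_pct / 100.0 * rng.uniform(0.8, 1.2)
                halfwidth = rng.uniform(0.08, 0.15)
                center = rng.uniform(0.05 + halfwidth, 0.95 - halfwidth)
                shape = shape - depth * _raised_cosine(t_frac, center, halfwidth)
        noise = 1.0 + params.noise_pct / 100.0 * rng.standard_normal(n_pts)
        volumes = np.maximum(base * shape * noise, 1e-6)

        trajectories.append(
            VolumeTrajectory(f"{params.stage}_HF{i:03d}", params.stage, t_min, volumes, cells)
        )
        labels.append(category)
    return trajectories, labels


def telogen_params(seed: int = 0, **overrides) -> VolumeSimParams:
    return replace(VolumeSimParams(seed=seed), **overrides)


def anagen_params(seed: int = 0, **overrides) -> VolumeSimParams:
    return replace(VolumeSimParams(seed=seed), **{**ANAGEN_PRESET, **overrides})


# --------------------------------------------------------------------------- #
# AFM force maps
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class AfmSimParams:
    """Force-map generator settings (one curve per grid point).

    ``e_true_pa`` is the region's modulus; ``e_sd_pa`` adds per-point
    heterogeneity.  The contact point is placed uniformly in the first third
    of the z ramp, exactly on the sampling grid, with a zero-slope baseline.
    """

    grid: int = 8
    region_size_um: float = 15.0
    e_true_pa: float = 747.3
    e_sd_pa: float = 0.0
    geometry: str = "sphere"
    tip_parameter: float = 1.0  # radius µm (sphere) or half-angle deg (cone)
    poisson: float = 0.5
    max_indent_nm: float = 500.0
    force_noise_pn: float = 0.0
    n_samples: int = 200
    region: str = "HG"
    seed: int = 0

    def validate(self) -> None:
        if self.e_true_pa <= 0:
            raise ParameterError("e_true_pa must be positive")
        if self.grid < 1:
            raise ParameterError("grid must be >= 1")
        if not 0 <= self.poisson <= 0.5:
            raise ParameterError("poisson ratio must lie in [0, 0.5]")
        if self.geometry not in ("sphere", "cone"):
            raise ParameterError("geometry must be 'sphere' or 'cone'")
        if self.max_indent_nm <= 0 or self.n_samples < 30:
            raise ParameterError("need positive indentation depth and >= 30 samples")


def gen_force_curve(
    e_pa: float, params: AfmSimParams, rng: np.random.Generator
) -> ForceCurve:
    """One synthetic approach curve with known modulus ``e_pa``."""
    k_geom, exponent = _geometry_prefactor(params.geometry, params.tip_parameter)
    dz = params.max_indent_nm / (params.n_samples * 2 / 3)
    n_pre = int(rng.integers(10, max(params.n_samples // 3, 11)))
    n_post = params.n_samples - n_pre
    z = np.arange(params.n_samples) * dz  # contact exactly at sample n_pre
    delta_m = np.concatenate([np.zeros(n_pre), (z[n_pre:] - z[n_pre]) * _NM])
    force_n = k_geom * e_pa / (1.0 - params.poisson**2) * delta_m**exponent
    force_pn = force_n / _PN
    if params.force_noise_pn > 0:
        force_pn = force_pn + params.force_noise_pn * rng.standard_normal(z.size)
    return ForceCurve(z, force_pn)


def gen_force_map(params: AfmSimParams) -> ForceMap:
    """An 8x8 (by default) map of synthetic curves with per-point truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.grid**2
    if params.e_sd_pa > 0:
        # tissue moduli are positive and right-skewed; moment-matched lognormal
        sigma2 = np.log1p((params.e_sd_pa / params.e_true_pa) ** 2)
        mu = np.log(params.e_true_pa) - sigma2 / 2.0
        e_true = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    else:
        e_true = np.full(n, params.e_true_pa)
    curves = [gen_force_curve(e, params, rng) for e in e_true]
    step = params.region_size_um / params.grid
    ij = np.indices((params.grid, params.grid)).reshape(2, -1).T
    positions = (ij + 0.5) * step
    return ForceMap(params.region, params.grid, params.region_size_um, curves, positions, e_true)


# --------------------------------------------------------------------------- #
# cell mechano-records
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class MechSimParams:
    """Per-cell F-actin / YAP generator with tunable inverse correlation.

    Stage defaults encode the observed structure: telogen cells carry strong
    cortical F-actin and a low nuclear/cytoplasmic YAP ratio, anagen cells the
    reverse.  Within each stage the two variables follow a Gaussian copula
    with correlation ``inverse_correlation_rho`` in [-1, 0].
    """

    n_cells_per_stage: int = 100
    telogen_factin: tuple[float, float] = (100.0, 15.0)  # mean, SD (a.u.)
    telogen_yap: tuple[float, float] = (1.0, 0.2)
    anagen_factin: tuple[float, float] = (60.0, 15.0)
    anagen_yap: tuple[float, float] = (2.0, 0.4)
    inverse_correlation_rho: float = -0.5
    seed: int = 0

    def validate(self) -> None:
        if not -1.0 <= self.inverse_correlation_rho <= 0.0:
            raise ParameterError("inverse_correlation_rho must lie in [-1, 0]")
        for name in ("telogen_factin", "telogen_yap", "anagen_factin", "anagen_yap"):
            if getattr(self, name)[1] < 0:
                raise ParameterError(f"{name}: SD must be non-negative")


def gen_cell_mech(params: MechSimParams) -> list[CellMechRecord]:
    """Correlated (F-actin, YAP-ratio) records for both stages."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    rho = params.inverse_correlation_rho
    records: list[CellMechRecord] = []
    for stage, (f_mu, f_sd), (y_mu, y_sd) in (
        ("telogen", params.telogen_factin, params.telogen_yap),
        ("anagen", params.anagen_factin, params.anagen_yap),
    ):
        n = params.n_cells_per_stage
        z1 = rng.standard_normal(n)
        if rho <= -1.0 + 1e-12:
            z2 = -z1  # exact anti-monotone pairing
        else:
            z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        factin = np.maximum(f_mu + f_sd * z1, 1e-3)
        yap = np.maximum(y_mu + y_sd * z2, 1e-3)
        for i in range(n):
            records.append(CellMechRecord(f"{stage}_{i:04d}", stage, float(factin[i]), float(yap[i])))
    return records


# --------------------------------------------------------------------------- #
# expression matrices
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ExprSimParams:
    """Negative-binomial gene x cell counts with a planted actin-set effect.

    ``actin_effect`` maps population label -> fold-change applied to the
    actin gene set before sampling (1.0 = no effect).  Dispersion is shared
    across genes, the standard droplet-data assumption.
    """

    populations: tuple[tuple[str, int], ...] = (
        ("HF-SC", 100),
        ("HG", 100),
        ("IFE_B", 100),
        ("SG", 100),
    )
    n_genes: int = 1000
    actin_set_size: int = 30
    actin_effect: tuple[tuple[str, float], ...] = (("HF-SC", 2.0),)
    nb_dispersion: float = 10.0
    library_size_range: tuple[float, float] = (8000.0, 12000.0)
    seed: int = 0

    def validate(self) -> None:
        if any(fc <= 0 for _, fc in self.actin_effect):
            raise ParameterError("fold-changes must be positive")
        if any(n <= 0 for _, n in self.populations):
            raise ParameterError("population cell counts must be positive")
        if self.actin_set_size >= self.n_genes:
            raise ParameterError("actin_set_size must be smaller than n_genes")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be positive")


def gen_expression(params: ExprSimParams):
    """Return (AnnData cells x genes, GeneSet) with population labels in .obs.

    Actin-set genes are drawn from the same base-expression distribution as
    the background, then scaled by each population's fold-change before NB
    sampling, so the null (all fold-changes 1) is exactly exchangeable.
    """
    import anndata as ad
    import pandas as pd
    from scipy import sparse

    from .actin import GeneSet

    params.validate()
    rng = np.random.default_rng(params.seed)

    actin_genes = [f"Actg{i:03d}" for i in range(params.actin_set_size)]
    background = [f"Gene{i:05d}" for i in range(params.n_genes - params.actin_set_size)]
    if set(actin_genes) & set(background):
        raise ParameterError("actin and background gene identifiers overlap")
    genes = actin_genes + background
    gene_is_actin = np.zeros(len(genes), dtype=bool)
    gene_is_actin[: params.actin_set_size] = True

    # base relative expression, lognormal across genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    effect = dict(params.actin_effect)

    blocks, labels, barcodes = [], [], []
    cell_idx = 0
    for pop, n_cells in params.populations:
        fc = effect.get(pop, 1.0)
        weights = base.copy()
        weights[gene_is_actin] *= fc
        probs = weights / weights.sum()
        lib = rng.uniform(*params.library_size_range, size=n_cells)
        mean = lib[:, None] * probs[None, :]
        r = params.nb_dispersion
        lam = rng.gamma(shape=r, scale=mean / r)
        counts = rng.poisson(lam)
        blocks.append(counts)
        labels.extend([pop] * n_cells)
        barcodes.extend(f"cell{cell_idx + i:05d}" for i in range(n_cells))
        cell_idx += n_cells

    x = sparse.csr_matrix(np.vstack(blocks))
    adata = ad.AnnData(
        X=x,
        obs=pd.DataFrame({"population": pd.Categorical(labels)}, index=barcodes),
        var=pd.DataFrame(index=genes),
    )
    return adata, GeneSet("actin", tuple(actin_genes))


# --------------------------------------------------------------------------- #
# recoil traces
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class RecoilSimParams:
    """Post-ablation recoil trace generator.

    The control defaults (A = 3 µm, tau = 10 s, v0 = 0.3 µm/s) and the
    treated preset (A = 1.5 µm, tau = 7.5 s, v0 = 0.2 µm/s) encode a -50%
    plateau and -33% initial-velocity effect, sampled over a 45-s window.
    """

    l0_um: float = 10.0
    a_um: float = 3.0
    tau_s: float = 10.0
    sample_rate_hz: float = 2.0
    duration_s: float = 45.0
    noise_um: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.tau_s <= 0:
            raise ParameterError("tau must be positive")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ParameterError("duration and sample rate must be positive")


TREATED_RECOIL_PRESET = dict(a_um=1.5, tau_s=7.5)


def gen_recoil(params: RecoilSimParams) -> RecoilTrace:
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(params.duration_s * params.sample_rate_hz) + 1
    t = np.arange(n) / params.sample_rate_hz
    l = params.l0_um + params.a_um * (1.0 - np.exp(-t / params.tau_s))
    if params.noise_um > 0:
        l = l + params.noise_um * rng.standard_normal(n)
    return RecoilTrace(t, np.maximum(l, 1e-6))


# --------------------------------------------------------------------------- #
# 3'UTRs with planted seed sites
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class UtrSimParams:
    """Random 3'UTRs with seed sites planted at known 1-based positions.

    ``planted_sites`` is a tuple of (utr_index, position, site_type).  With
    ``screen_chance=True`` background sequence is redrawn until it contains no
    chance seed matches, so planted sites are the only hits.
    """

    mirna_sequence: str = MIR205_SEQUENCE
    n_utrs: int = 50
    utr_length_range: tuple[int, int] = (200, 1000)
    planted_sites: tuple[tuple[int, int, str], ...] = ()
    background_gc: float = 0.45
    screen_chance: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.background_gc < 1.0:
            raise ParameterError("background_gc must lie in (0, 1)")
        for utr_idx, _pos, site_type in self.planted_sites:
            if site_type not in tg.SITE_TYPES:
                raise ParameterError(f"unknown site type {site_type!r}")
            if not 0 <= utr_idx < self.n_utrs:
                raise ParameterError("planted site references a missing UTR")


def site_sequence(mirna: tg.MicroRNA, site_type: str) -> str:
    """The exact UTR match sequence (5'->3') for one site type."""
    core = tg.reverse_complement(mirna.sequence[1:7])
    m8 = tg._COMPLEMENT[mirna.sequence[7]]
    return {
        "6mer": core,
        "7mer-m8": m8 + core,
        "7mer-A1": core + "A",
        "8mer": m8 + core + "A",
    }[site_type]


def gen_utrs(params: UtrSimParams):
    """Return (list of UtrRecord, truth table, chance-site log).

    The truth table is a list of dicts (gene, position, site_type); the chance
    log records seed matches that arose in the random background (empty when
    ``screen_chance`` is on).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    mirna = tg.MicroRNA("query", params.mirna_sequence)
    alphabet = np.array(list("ACGU"))
    gc = params.background_gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    planted_by_utr: dict[int, list[tuple[int, str]]] = {}
    for utr_idx, pos, site_type in params.planted_sites:
        planted_by_utr.setdefault(utr_idx, []).append((pos, site_type))

    records: list[tg.UtrRecord] = []
    truth: list[dict] = []
    chance_log: list[dict] = []
    for i in range(params.n_utrs):
        length = int(rng.integers(params.utr_length_range[0], params.utr_length_range[1] + 1))
        planted = planted_by_utr.get(i, [])
        for pos, site_type in planted:
            if not 1 <= pos <= length - len(site_sequence(mirna, site_type)) + 1:
                raise ParameterError(
                    f"site {site_type} at position {pos} does not fit in UTR {i} (len {length})"
                )
        planted_spans = []
        for pos, site_type in planted:
            s = pos - 1
            planted_spans.append((s, s + len(site_sequence(mirna, site_type))))

        for attempt in range(200):
            seq = rng.choice(alphabet, size=length, p=probs)
            for (pos, site_type) in planted:
                s = pos - 1
                ss = site_sequence(mirna, site_type)
                seq[s : s + len(ss)] = list(ss)
            record = tg.UtrRecord(f"utr{i:04d}", "".join(seq))
            hits = tg.find_seed_sites(mirna, record)
            chance = [
                h for h in hits
                if not any(s < h.end and h.start - 1 < e for s, e in planted_spans)
            ]
            if not params.screen_chance or not chance:
                break
        else:
            raise ParameterError(f"could not screen chance sites out of UTR {i}")
        records.append(record)
        for pos, site_type in planted:
            truth.append({"gene": record.gene, "position": pos, "site_type": site_type})
        for h in chance:
            chance_log.append(
                {"gene": record.gene, "position": h.start, "site_type": h.site_type}
            )
    return records, truth, chance_log
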