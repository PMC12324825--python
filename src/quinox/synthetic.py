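"""Synthetic inputs with known ground truth for both pipeline branches.

Two generators: MS1 feature tables emulating quinone homologue series
(ppm-scale mass error, three positive-ESI adducts per species, uniform decoy
features kept well away from any candidate), and noisy cyclic voltammograms
produced by the forward surface-redox model plus a linear capacitive ramp
and additive Gaussian current noise. Both are bit-reproducible for a fixed
seed and return their ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .adducts import adduct_mz, get_adduct
from .annotate import MSFeature, SearchSpace
from .species import QuinoneClass, QuinoneSpecies
from .voltammetry import SurfaceRedoxParams, Voltammogram, simulate_cv

__all__ = [
    "FeatureTableSpec",
    "CVSpec",
    "gen_feature_table",
    "gen_table1_fixture",
    "gen_voltammogram",
    "NITRIFIER_ABUNDANCES",
]

_MPQ = QuinoneClass.METHYL_PLASTOQUINONE

# Published methyl-plastoquinone compositions of the two nitrifier isolates
# (percent of summed combined-adduct XIC peak area; values below the 0.1%
# reporting floor encoded as 0.05).
NITRIFIER_ABUNDANCES: dict[str, dict[tuple[int, int], float]] = {
    "N_inopinata": {
        (6, 6): 1.6, (6, 5): 0.3, (7, 7): 40.0, (7, 6): 1.4, (8, 8): 45.3,
        (8, 7): 10.8, (9, 9): 0.6, (9, 8): 0.1, (10, 10): 0.05,
    },
    "N_moscoviensis": {
        (7, 7): 0.1, (8, 8): 2.1, (9, 9): 67.1, (10, 10): 29.2, (11, 11): 1.5,
    },
}


@dataclass(frozen=True)
class FeatureTableSpec:
    """Recipe for a synthetic MS1 feature table.

    ``abundances`` maps sample id → {species: relative abundance %}; each
    sample's abundances must sum to 100 (±1e-6). Every species emits one
    feature per adduct with area = scale × abundance × adduct split, at the
    theoretical m/z perturbed by Normal(0, σ) mmu. Decoy features are drawn
    uniformly over ``decoy_mz_range`` and rejected within 5 mmu of any
    candidate of the default search space.
    """

    abundances: dict[str, dict[QuinoneSpecies, float]]
    adduct_split: tuple[float, float, float] = (0.80, 0.15, 0.05)  # H, NH4, Na
    mass_error_mmu: float = 0.5
    n_decoys: int = 5
    decoy_mz_range: tuple[float, float] = (350.0, 1000.0)
    area_scale: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_error_mmu < 0:
            raise ValueError("mass-error sigma must be >= 0")
        if abs(sum(self.adduct_split) - 1.0) > 1e-9:
            raise ValueError("adduct split must sum to 1")
        for sample, ab in self.abundances.items():
            total = sum(ab.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(
                    f"abundances for sample {sample!r} sum to {total}, not 100"
                )


_ADDUCT_NAMES = ("[M+H]+", "[M+NH4]+", "[M+Na]+")


def gen_feature_table(
    spec: FeatureTableSpec,
) -> tuple[list[MSFeature], dict[int, tuple[str, QuinoneSpecies | None, str | None]]]:
    """Generate features and a ground-truth map.

    Returns the feature list and a map feature-index → (sample, species,
    adduct name); decoys map to (sample, None, None).
    """
    rng = np.random.default_rng(spec.seed)
    features: list[MSFeature] = []
    truth: dict[int, tuple[str, QuinoneSpecies | None, str | None]] = {}
    cand_mz = np.array([c[2] for c in SearchSpace().candidates()])
    for sample in sorted(spec.abundances):
        for sp in sorted(spec.abundances[sample]):
            pct = spec.abundances[sample][sp]
            neutral = sp.formula()
            for aname, split in zip(_ADDUCT_NAMES, spec.adduct_split):
                if split <= 0:
                    continue
                mz_true = adduct_mz(neutral, get_adduct(aname))
                mz = mz_true + rng.normal(0.0, spec.mass_error_mmu) * 1e-3
                area = spec.area_scale * pct / 100.0 * split
                truth[len(features)] = (sample, sp, aname)
                features.append(
                    MSFeature(sample=sample, mz=mz, area=area, rt_min=10.0 + sp.n)
                )
        for _ in range(spec.n_decoys):
            for attempt in range(1000):
                mz = rng.uniform(*spec.decoy_mz_range)
                if np.min(np.abs(mz - cand_mz)) >= 5e-3:
                    break
            else:
                raise RuntimeError(
                    "could not place a decoy >= 5 mmu from every candidate "
                    "after 1000 draws; widen decoy_mz_range"
                )
            truth[len(features)] = (sample, None, None)
            features.append(
                MSFeature(sample=sample, mz=mz, area=spec.area_scale * 1e-3,
                          rt_min=float(rng.uniform(5, 60)))
            )
    return features, truth


def gen_table1_fixture(
    mass_error_mmu: float = 0.0,
    n_decoys: int = 0,
    seed: int = 0,
) -> dict[str, FeatureTableSpec]:
    """Feature-table specs encoding the two nitrifier quinone profiles.

    The printed percentages (with "<0.1" encoded as 0.05, "n.d." omitted)
    are renormalised to sum to exactly 100 per sample.
    """
    out = {}
    for sample, ab in NITRIFIER_ABUNDANCES.items():
        total = sum(ab.values())
        norm = {
            QuinoneSpecies(_MPQ, n, m): 100.0 * pct / total
            for (n, m), pct in ab.items()
        }
        out[sample] = FeatureTableSpec(
            abundances={sample: norm},
            mass_error_mmu=mass_error_mmu,
            n_decoys=n_decoys,
            seed=seed,
        )
    return out


@dataclass(frozen=True)
class CVSpec:
    """Recipe for a synthetic voltammogram at the study's cell conditions.

    Defaults mirror the measurement setup: 20 mV s⁻¹ sweep, 0.126 cm²
    electrode, 303 K cell, two-electron couple with a formal potential of
    −0.142 V vs Ag|AgCl (+57 mV vs SHE) and an attractive interaction on
    the oxidised form producing the sharp-cathodic/broad-anodic shape.
    """

    params: SurfaceRedoxParams = field(
        default_factory=lambda: SurfaceRedoxParams(
            e0=-0.142, n_e=2, gamma_T=1e-10, k_s=5.0, alpha=0.5,
            a_ox=0.9, a_red=0.0, temperature=303.0, area_cm2=0.126,
        )
    )
    e_start: float = 0.10
    e_vertex: float = -0.45
    scan_rate: float = 0.02
    points_per_segment: int = 276  # 2 mV spacing, as a digitised instrument file
    noise_sigma: float = 0.0  # A
    baseline: tuple[float, float] = (0.0, 0.0)  # intercept A, slope A/V
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        lo, hi = min(self.e_start, self.e_vertex), max(self.e_start, self.e_vertex)
        if not (lo <= self.params.e0 - 0.15 and hi >= self.params.e0 + 0.15):
            raise ValueError("sweep window must bracket E0' by >= 0.15 V")

    def with_snr(self, snr: float) -> "CVSpec":
        """Set the noise sigma so the cathodic peak has the given SNR."""
        clean = simulate_cv(
            self.params, self.e_start, self.e_vertex,
            scan_rate=self.scan_rate, points_per_segment=self.points_per_segment,
        )
        i_pk = float(np.max(np.abs(clean.current)))
        return replace(self, noise_sigma=i_pk / snr)


def gen_voltammogram(spec: CVSpec) -> tuple[Voltammogram, SurfaceRedoxParams]:
    """Forward-simulate a voltammogram, add baseline ramp and noise.

    Returns the noisy voltammogram and the generating parameters.
    """
    v = simulate_cv(
        spec.params, spec.e_start, spec.e_vertex,
        scan_rate=spec.scan_rate, points_per_segment=spec.points_per_segment,
    )
    rng = np.random.default_rng(spec.seed)
    b0, b1 = spec.baseline
    current = v.current + b0 + b1 * v.potential
    if spec.noise_sigma > 0:
        current = current + rng.normal(0.0, spec.noise_sigma, size=len(current))
    noisy = Voltammogram(
        v.potential, current, v.segment,
        scan_rate=v.scan_rate, temperature=v.temperature, area_cm2=v.area_cm2,
    )
    return noisy, spec.params
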