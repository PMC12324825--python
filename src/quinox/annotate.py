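"""Exact-mass annotation and quantification of quinone homologue series.

Measured MS1 features are matched against a candidate grid of quinone ions
(class × chain length × unsaturation × adduct) by mass deviation
Δmmu = (measured − calculated) × 1000. A feature is assigned to the candidate
with the smallest |Δmmu| inside the tolerance; ties are broken by lower
chain length, then lower unsaturation, then class name — deterministic.
Unassigned features are kept and flagged, never dropped.

Quantification follows the combined-adduct extracted-ion-chromatogram
convention: per sample, peak areas of all adducts of a species are summed
and expressed as a percentage of the summed area over all assigned species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .adducts import ADDUCTS, Adduct, adduct_mz, get_adduct
from .species import QuinoneClass, QuinoneSpecies

__all__ = [
    "MSFeature",
    "AnnotationRecord",
    "SearchSpace",
    "delta_mmu",
    "annotate_features",
    "relative_abundance",
    "read_feature_table",
    "write_feature_table",
    "abundance_report",
    "write_report",
]


@dataclass(frozen=True)
class MSFeature:
    """One centroided MS1 feature: a measured ion in one sample."""

    sample: str
    mz: float
    area: float
    rt_min: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")


@dataclass(frozen=True)
class AnnotationRecord:
    """A feature together with its species/adduct assignment (or lack of one)."""

    feature: MSFeature
    species: QuinoneSpecies | None = None
    adduct: Adduct | None = None
    calculated_mz: float | None = None
    delta_mmu: float | None = None
    relative_abundance: float | None = None

    @property
    def is_assigned(self) -> bool:
        return self.species is not None


@dataclass(frozen=True)
class SearchSpace:
    """Candidate grid for annotation.

    Defaults bracket the homologue series seen in nitrifier lipid extracts:
    chains of 4–12 isoprene units, unsaturation from fully unsaturated down
    to two bonds fewer, all three positive-ESI adducts, all four classes.
    """

    classes: tuple[QuinoneClass, ...] = tuple(QuinoneClass)
    n_range: tuple[int, int] = (4, 12)
    m_below_n: int = 2  # m from max(0, n - m_below_n) .. n
    adducts: tuple[str, ...] = tuple(ADDUCTS)

    def candidates(self) -> list[tuple[QuinoneSpecies, Adduct, float]]:
        out = []
        for cls in self.classes:
            for n in range(self.n_range[0], self.n_range[1] + 1):
                for m in range(max(0, n - self.m_below_n), n + 1):
                    sp = QuinoneSpecies(cls, n, m)
                    neutral = sp.formula()
                    for aname in self.adducts:
                        a = get_adduct(aname)
                        out.append((sp, a, adduct_mz(neutral, a)))
        if not out:
            raise ValueError("empty search space")
        return out


def delta_mmu(measured: float, calculated: float) -> float:
    """Signed mass deviation in milli-mass-units: (measured − calculated) × 1000."""
    return (measured - calculated) * 1000.0


def annotate_features(
    features: list[MSFeature],
    space: SearchSpace | None = None,
    tolerance: float = 2.0,
    unit: str = "mmu",
) -> list[AnnotationRecord]:
    """Assign each feature to the closest candidate ion within tolerance.

    Parameters
    ----------
    features
        Measured MS1 features (any number of samples).
    space
        Candidate grid; defaults to :class:`SearchSpace` defaults.
    tolerance
        Matching tolerance, > 0.
    unit
        ``"mmu"`` (milli-mass-units, default) or ``"ppm"``.

    Returns
    -------
    One record per input feature, in input order; unassigned features carry
    ``species=None`` and ``is_assigned`` False.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    if unit not in ("mmu", "ppm"):
        raise ValueError(f"tolerance unit must be 'mmu' or 'ppm', got {unit!r}")
    if not features:
        return []
    cands = (space or SearchSpace()).candidates()
    cand_mz = np.array([c[2] for c in cands])

    records: list[AnnotationRecord] = []
    for f in features:
        dev_mmu = (f.mz - cand_mz) * 1000.0
        tol_mmu = tolerance if unit == "mmu" else tolerance * f.mz / 1000.0
        inside = np.flatnonzero(np.abs(dev_mmu) <= tol_mmu)
        if inside.size == 0:
            records.append(AnnotationRecord(feature=f))
            continue
        best = min(
            inside,
            key=lambda i: (
                abs(dev_mmu[i]),
                cands[i][0].n,
                cands[i][0].m,
                cands[i][0].quinone_class.value,
                cands[i][1].name,
            ),
        )
        sp, a, mz_calc = cands[best]
        records.append(
            AnnotationRecord(
                feature=f,
                species=sp,
                adduct=a,
                calculated_mz=mz_calc,
                delta_mmu=delta_mmu(f.mz, mz_calc),
            )
        )
    return records


def relative_abundance(
    records: list[AnnotationRecord],
) -> list[AnnotationRecord]:
    """Fill per-sample relative abundances (%) on assigned records.

    Per sample, areas are summed per species across its adducts and divided
    by the total area over all assigned species. Unassigned records pass
    through unchanged with ``relative_abundance`` None.
    """
    assigned = [r for r in records if r.is_assigned]
    if not assigned:
        raise ValueError("no assigned annotations to quantify")
    samples: dict[str, float] = {}
    for r in assigned:
        samples[r.feature.sample] = samples.get(r.feature.sample, 0.0) + r.feature.area
    for s, total in samples.items():
        if total <= 0:
            raise ValueError(f"all-zero total peak area in sample {s!r}")
    # per (sample, species) area
    sp_area: dict[tuple[str, QuinoneSpecies], float] = {}
    for r in assigned:
        key = (r.feature.sample, r.species)
        sp_area[key] = sp_area.get(key, 0.0) + r.feature.area
    out = []
    for r in records:
        if r.is_assigned:
            key = (r.feature.sample, r.species)
            pct = 100.0 * sp_area[key] / samples[r.feature.sample]
            out.append(replace(r, relative_abundance=pct))
        else:
            out.append(r)
    return out


def abundance_table(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Long-form per-sample species percentages from quantified records."""
    rows = {}
    for r in records:
        if r.is_assigned and r.relative_abundance is not None:
            rows[(r.feature.sample, r.species)] = r.relative_abundance
    return pd.DataFrame(
        [
            {"sample": s, "species": sp.name, "n": sp.n, "m": sp.m, "percent": pct}
            for (s, sp), pct in sorted(
                rows.items(), key=lambda kv: (kv[0][0], kv[0][1].n, -kv[0][1].m)
            )
        ]
    )


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_feature_table(path: str | Path | io.TextIOBase) -> list[MSFeature]:
    """Read a feature table (comma- or tab-delimited, auto-detected).

    Required columns: ``sample``, ``mz``, ``area``; optional ``rt_min``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"sample", "mz", "area"} - set(df.columns)
    if missing:
        raise ValueError(
            f"feature table is missing required column(s): {', '.join(sorted(missing))}"
        )
    feats = []
    for i, row in df.iterrows():
        try:
            feats.append(
                MSFeature(
                    sample=str(row["sample"]),
                    mz=float(row["mz"]),
                    area=float(row["area"]),
                    rt_min=float(row["rt_min"]) if "rt_min" in df.columns and pd.notna(row["rt_min"]) else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"feature table line {i + 2}: {exc}") from exc
    return feats


def write_feature_table(features: list[MSFeature], path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "sample": [f.sample for f in features],
            "mz": [f.mz for f in features],
            "rt_min": [f.rt_min for f in features],
            "area": [f.area for f in features],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def abundance_report(
    records: list[AnnotationRecord],
    report_floor: float = 0.1,
) -> pd.DataFrame:
    """Annotation report shaped like the classical quinone-composition tables.

    One row per detected species, sorted by chain length then decreasing
    unsaturation; columns: species name, accurate mass (measured [M+H]+ m/z),
    AEC ([M+H]+ formula), Δ mmu of the [M+H]+ feature, then one relative-
    abundance column per sample. Species never seen in a sample are "n.d.";
    species below ``report_floor`` percent show as ``"< {floor}"`` — two
    distinct states.
    """
    assigned = [r for r in records if r.is_assigned]
    if not assigned:
        raise ValueError("nothing to report: no assigned annotations")
    samples = sorted({r.feature.sample for r in assigned})
    species = sorted({r.species for r in assigned}, key=lambda s: (s.n, -s.m, s.name))
    pct: dict[tuple[str, QuinoneSpecies], float] = {}
    for r in assigned:
        if r.relative_abundance is not None:
            pct[(r.feature.sample, r.species)] = r.relative_abundance
    rows = []
    for sp in species:
        # prefer the protonated ion for the mass columns, as in the tables
        proto = [r for r in assigned if r.species == sp and r.adduct.name == "[M+H]+"]
        any_r = proto[0] if proto else [r for r in assigned if r.species == sp][0]
        row = {
            "Quinone": sp.name,
            "Accurate mass (m/z)": f"{any_r.feature.mz:.3f}",
            "AEC": sp.protonated_formula().formula(),
            "Delta mmu": f"{any_r.delta_mmu + 0.0:.1f}".replace("-0.0", "0.0"),
        }
        for s in samples:
            if (s, sp) not in pct:
                row[s] = "n.d."
            elif pct[(s, sp)] < report_floor:
                row[s] = f"< {report_floor:g}"
            else:
                row[s] = f"{pct[(s, sp)]:.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    report.to_csv(path, sep=sep, index=False)
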