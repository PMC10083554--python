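"""Catalog of bilaterally paired brain regional measures.

The measure set mirrors a standard FreeSurfer-style segmentation: 34
Desikan-Killiany (DK) cortical parcels with thickness and surface-area
measures plus the hemisphere-level averages (35 + 35), and 8 subcortical
volumes, for 78 paired measures in total. The two hemisphere-average
measures are excluded from the multivariate arm, leaving 76 regional
asymmetry indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "RegionEntry",
    "RegionCatalog",
    "DK_REGIONS",
    "SUBCORTICAL_REGIONS",
    "default_catalog",
]

#: The 34 bilaterally paired Desikan-Killiany cortical parcels.
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: The 8 bilaterally paired subcortical structures (aseg-style volumes).
SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "lateralventricle",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

# Rough per-structure volume scales (mm^3) for the synthetic generator.
_SUBCORTICAL_MEANS = {
    "lateralventricle": 7000.0,
    "thalamus": 7500.0,
    "caudate": 3700.0,
    "putamen": 5200.0,
    "pallidum": 1800.0,
    "hippocampus": 4100.0,
    "amygdala": 1650.0,
    "accumbens": 600.0,
}


@dataclass(frozen=True)
class RegionEntry:
    """One bilaterally paired measure.

    ``baseline_mean_ai`` is the population-average asymmetry index
    (positive = leftward) and ``baseline_ai_sd`` the between-individual
    AI standard deviation used to express diagnosis effects on the
    Cohen's d scale.
    """

    measure_id: str
    family: str  # thickness | area | subcortical
    is_hemisphere_average: bool
    baseline_bilateral_mean: float  # mm, mm^2 or mm^3
    baseline_bilateral_sd: float
    baseline_mean_ai: float
    baseline_ai_sd: float

    def __post_init__(self) -> None:
        if self.family not in ("thickness", "area", "subcortical"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.baseline_bilateral_mean <= 0:
            raise ValueError(
                f"{self.measure_id}: baseline bilateral mean must be positive"
            )
        if abs(self.baseline_mean_ai) >= 2:
            raise ValueError(f"{self.measure_id}: |baseline mean AI| must be < 2")
        if self.baseline_ai_sd <= 0:
            raise ValueError(f"{self.measure_id}: baseline AI sd must be positive")


@dataclass(frozen=True)
class RegionCatalog:
    """The full set of 78 paired measures grouped into three FDR families."""

    entries: tuple[RegionEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        counts = {"thickness": 0, "area": 0, "subcortical": 0}
        hemi = []
        for e in self.entries:
            counts[e.family] += 1
            if e.is_hemisphere_average:
                hemi.append(e)
        if (counts["thickness"], counts["area"], counts["subcortical"]) != (35, 35, 8):
            raise ValueError(
                "catalog must hold 35 thickness, 35 area and 8 subcortical "
                f"entries; got {counts}"
            )
        if len(hemi) != 2 or {e.family for e in hemi} != {"thickness", "area"}:
            raise ValueError(
                "exactly one thickness and one area hemisphere-average entry required"
            )

    @property
    def measure_ids(self) -> list[str]:
        return [e.measure_id for e in self.entries]

    @property
    def families(self) -> dict[str, str]:
        """measure_id -> family."""
        return {e.measure_id: e.family for e in self.entries}

    @property
    def multivariate_ids(self) -> list[str]:
        """The 76 regional measures eligible for the multivariate arm."""
        return [e.measure_id for e in self.entries if not e.is_hemisphere_average]

    def entry(self, measure_id: str) -> RegionEntry:
        for e in self.entries:
            if e.measure_id == measure_id:
                return e
        raise KeyError(measure_id)


def default_catalog() -> RegionCatalog:
    """Build the default 78-measure catalog.

    Baseline scales are order-of-magnitude FreeSurfer values: cortical
    thickness ~2.5 mm, regional surface areas 300-8,000 mm^2, subcortical
    volumes 0.6-7.5 cm^3. Baseline mean AIs are small (|AI| <= 0.05 for
    thickness, <= 0.1 for area and volume) with alternating sign across
    the parcel list so both leftward and rightward regions occur; AI
    standard deviations are set near values typical of regional thickness
    (~0.05-0.09) and area/volume (~0.06-0.10) asymmetry.
    """
    entries: list[RegionEntry] = []
    for i, region in enumerate(DK_REGIONS):
        sign = 1.0 if i % 2 == 0 else -1.0
        # deterministic, region-indexed spread of baselines
        entries.append(
            RegionEntry(
                measure_id=f"thick_{region}",
                family="thickness",
                is_hemisphere_average=False,
                baseline_bilateral_mean=2.2 + 0.02 * (i % 10),
                baseline_bilateral_sd=0.15,
                baseline_mean_ai=sign * (0.005 + 0.001 * (i % 5)),
                baseline_ai_sd=0.05 + 0.001 * (i % 8),
            )
        )
    entries.append(
        RegionEntry(
            measure_id="thick_hemisphere_mean",
            family="thickness",
            is_hemisphere_average=True,
            baseline_bilateral_mean=2.45,
            baseline_bilateral_sd=0.10,
            baseline_mean_ai=0.004,
            baseline_ai_sd=0.02,
        )
    )
    for i, region in enumerate(DK_REGIONS):
        sign = -1.0 if i % 2 == 0 else 1.0
        entries.append(
            RegionEntry(
                measure_id=f"area_{region}",
                family="area",
                is_hemisphere_average=False,
                baseline_bilateral_mean=400.0 + 180.0 * (i % 12),
                baseline_bilateral_sd=60.0 + 20.0 * (i % 12),
                baseline_mean_ai=sign * (0.01 + 0.002 * (i % 6)),
                baseline_ai_sd=0.07 + 0.002 * (i % 6),
            )
        )
    entries.append(
        RegionEntry(
            measure_id="area_hemisphere_total",
            family="area",
            is_hemisphere_average=True,
            baseline_bilateral_mean=90000.0,
            baseline_bilateral_sd=8000.0,
            baseline_mean_ai=0.006,
            baseline_ai_sd=0.02,
        )
    )
    for i, region in enumerate(SUBCORTICAL_REGIONS):
        sign = 1.0 if i % 2 == 0 else -1.0
        mean = _SUBCORTICAL_MEANS[region]
        entries.append(
            RegionEntry(
                measure_id=f"vol_{region}",
                family="subcortical",
                is_hemisphere_average=False,
                baseline_bilateral_mean=mean,
                baseline_bilateral_sd=0.12 * mean,
                baseline_mean_ai=sign * (0.02 + 0.005 * (i % 4)),
                baseline_ai_sd=0.08 + 0.004 * (i % 4),
            )
        )
    return RegionCatalog(entries=tuple(entries))
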