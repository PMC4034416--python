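"""Ground-truth retinotopic atlas and expected-subregion rules.

The atlas plays the role of an individual's fMRI retinotopic map: every
vertex of the synthetic source space is labeled with a visual area (V1
medial, V2/V3 flanking strips, V3A dorsal-anterior, or none), an angular
polarity (dorsal = lower visual field, ventral = upper visual field) and an
eccentricity band (1 = foveal at the occipital pole, 3 = peripheral,
increasing along the posterior→anterior sheet axis).

Retinotopy rules encoded here: left/right visual field → contralateral
hemisphere; upper field → ventral bank; lower field → dorsal bank; ring of
eccentricity k → band k across V1–V3 bilaterally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SourceSpace

AREAS = ("V1", "V2", "V3")

# chance levels (percent) for the three kinds of accuracy comparison
CHANCE_ANGULAR = 25.0       # four angular subregions per area (V1-V3)
CHANCE_V3A = 50.0           # two subregions (left/right hemisphere) only
CHANCE_ECCENTRICITY = 100.0 / 3.0  # three eccentricity bands


class ResolutionTooCoarseError(ValueError):
    """A required retinotopic subregion is empty at this resolution."""


class UnsupportedCombinationError(ValueError):
    """Stimulus and ROI selector are incompatible."""


@dataclass(frozen=True)
class RetinotopicAtlas:
    """Per-vertex ground-truth labels on a :class:`SourceSpace`."""

    space: SourceSpace
    df: pd.DataFrame  # vertex_id, hemi, area, polarity, ecc_band

    @property
    def area(self) -> np.ndarray:
        return self.df["area"].to_numpy()

    @property
    def polarity(self) -> np.ndarray:
        return self.df["polarity"].to_numpy()

    @property
    def ecc_band(self) -> np.ndarray:
        return self.df["ecc_band"].to_numpy()

    @property
    def hemi(self) -> np.ndarray:
        return self.df["hemi"].to_numpy()

    def mask(self, area=None, hemi=None, polarity=None, band=None) -> np.ndarray:
        """Boolean vertex mask; ``area`` may be a tuple of areas."""
        m = np.ones(len(self.df), dtype=bool)
        if area is not None:
            areas = (area,) if isinstance(area, str) else tuple(area)
            m &= np.isin(self.area, areas)
        if hemi is not None:
            m &= self.hemi == hemi
        if polarity is not None:
            m &= self.polarity == polarity
        if band is not None:
            m &= self.ecc_band == band
        return m


def build_retinotopic_atlas(
    space: SourceSpace,
    band_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> RetinotopicAtlas:
    """Assign area / polarity / eccentricity labels to a source space.

    V1 occupies the medial third of each bank (smallest mediolateral
    coordinate ``w``), V2 and V3 the flanking strips; eccentricity bands
    partition the posterior→anterior coordinate ``u`` according to
    ``band_fractions``.
    """
    fr = np.asarray(band_fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("band_fractions must be three positive proportions summing to 1")

    df = space.df
    n = len(df)
    area = np.full(n, "none", dtype=object)
    polarity = np.full(n, "na", dtype=object)
    band = np.zeros(n, dtype=int)  # 0 = na

    main = (df["sheet"] == "main").to_numpy()
    w = df["w"].to_numpy()
    u = df["u"].to_numpy()
    area[main & (w < 1 / 3)] = "V1"
    area[main & (w >= 1 / 3) & (w < 2 / 3)] = "V2"
    area[main & (w >= 2 / 3)] = "V3"
    polarity[main] = df.loc[main, "bank"].to_numpy()
    edges = np.cumsum(fr)[:2]
    band[main] = 1 + np.searchsorted(edges + 1e-12, u[main])

    v3a = (df["sheet"] == "v3a").to_numpy()
    area[v3a] = "V3A"

    out = pd.DataFrame(
        {
            "vertex_id": df["vertex_id"].to_numpy(),
            "hemi": df["hemi"].to_numpy(),
            "area": area,
            "polarity": polarity,
            "ecc_band": band,
        }
    )
    atlas = RetinotopicAtlas(space=space, df=out)
    _validate(atlas)
    return atlas


def _validate(atlas: RetinotopicAtlas) -> None:
    for a in AREAS:
        for h in ("L", "R"):
            for p in ("dorsal", "ventral"):
                if not atlas.mask(area=a, hemi=h, polarity=p).any():
                    raise ResolutionTooCoarseError(
                        f"subregion {a}/{h}/{p} is empty; increase resolution"
                    )
            for b in (1, 2, 3):
                if not atlas.mask(area=a, hemi=h, band=b).any():
                    raise ResolutionTooCoarseError(
                        f"eccentricity band {b} of {a}/{h} is empty; "
                        "increase resolution"
                    )
    for h in ("L", "R"):
        if not atlas.mask(area="V3A", hemi=h).any():
            raise ResolutionTooCoarseError(f"V3A/{h} is empty")


# ---------------------------------------------------------------------------
# expected-subregion rules


@dataclass(frozen=True)
class ExpectedRegion:
    """Ground-truth-correct region for one stimulus × ROI-selector pair."""

    expected: np.ndarray  # vertices that count as correctly localized
    roi: np.ndarray       # vertices over which accuracy is evaluated
    chance: float         # percent

    def __post_init__(self):
        if not (self.expected & self.roi).sum() == self.expected.sum():
            raise ValueError("expected subregion must be contained in the ROI")


def _contralateral(stimulus) -> str:
    if stimulus.family == "quadrant":
        return "L" if stimulus.quadrant_pos in ("UR", "LR") else "R"
    if stimulus.family == "quarter_ring":
        return "L"  # quarter-rings are confined to the right visual hemifield
    raise UnsupportedCombinationError("rings are bilateral; no contralateral side")


def _field_polarity(stimulus) -> str:
    if stimulus.family == "quadrant":
        return "ventral" if stimulus.quadrant_pos in ("UL", "UR") else "dorsal"
    if stimulus.family == "quarter_ring":
        return "ventral" if stimulus.field_half == "upper_right" else "dorsal"
    raise UnsupportedCombinationError("rings span both field polarities")


def expected_subregion(stimulus, atlas: RetinotopicAtlas, selector) -> ExpectedRegion:
    """Resolve a stimulus × selector pair to (expected, ROI, chance).

    ``selector`` is either the name of a visual area (``"V1"``..``"V3A"``:
    angular accuracy within that area), ``"angular"`` (angular accuracy
    across V1–V3 combined) or ``"eccentricity"`` / ``("eccentricity", hemi)``
    (band accuracy across V1–V3; for quarter-rings evaluated inside the
    stimulated angular subregion).
    """
    hemi_restrict = None
    if isinstance(selector, tuple):
        selector, hemi_restrict = selector

    if selector in ("V1", "V2", "V3"):
        if stimulus.family == "ring":
            raise UnsupportedCombinationError(
                "rings are evaluated by eccentricity band, not angular subregion"
            )
        roi = atlas.mask(area=selector)
        expected = roi & atlas.mask(
            hemi=_contralateral(stimulus), polarity=_field_polarity(stimulus)
        )
        return ExpectedRegion(expected, roi, CHANCE_ANGULAR)

    if selector == "V3A":
        if stimulus.family != "quadrant":
            raise UnsupportedCombinationError(
                "V3A has angular (left/right) subregions only; quadrants only"
            )
        roi = atlas.mask(area="V3A")
        expected = roi & atlas.mask(hemi=_contralateral(stimulus))
        return ExpectedRegion(expected, roi, CHANCE_V3A)

    if selector == "angular":
        roi = atlas.mask(area=AREAS)
        expected = roi & atlas.mask(
            hemi=_contralateral(stimulus), polarity=_field_polarity(stimulus)
        )
        return ExpectedRegion(expected, roi, CHANCE_ANGULAR)

    if selector == "eccentricity":
        if stimulus.family == "quadrant":
            raise UnsupportedCombinationError(
                "quadrants span all eccentricities; band accuracy undefined"
            )
        if stimulus.family == "ring":
            roi = atlas.mask(area=AREAS, hemi=hemi_restrict)
        else:  # quarter-ring: evaluate within the stimulated angular subregion
            roi = atlas.mask(
                area=AREAS,
                hemi=_contralateral(stimulus),
                polarity=_field_polarity(stimulus),
            )
        expected = roi & (atlas.ecc_band == stimulus.ecc)
        return ExpectedRegion(expected, roi, CHANCE_ECCENTRICITY)

    raise ValueError(f"unknown ROI selector: {selector!r}")
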