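"""Pipeline configuration shared by alignment and semilandmark extraction."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PipelineConfig:
    """Every fraction and tolerance of the morphometric pipeline.

    Defaults are the published recipe: 50 slices of thickness 0.25% of the
    bone length, 7 sampling lines per slice with a 4% projection window,
    the bounding-rectangle band at 15.00-15.25% of the length, and 10% end
    slabs for the end-centroid registration.

    Attributes
    ----------
    n_slices : int
        Number of evenly spaced cross-sectional slices.
    slice_thickness_frac : float
        Slice thickness as a fraction of the z-axis length.
    n_lines : int
        Number of interior sampling lines per slice (parallel to y).
    projection_tol_frac : float
        Half-width of the projection window around each line, as a fraction
        of the slice's x-extent.
    mbr_band : (float, float)
        Fractional z-band whose minimum bounding rectangle fixes the x-axis.
    end_frac : float
        Fraction of the provisional z-extent sliced out at each end for the
        end-centroid registration.
    hull_centroid_mode : str
        'volume' (volume-weighted centroid of the hull polyhedron, default)
        or 'vertices' (plain mean of hull vertices).
    proximal_end : str
        'auto' picks the end slab with the larger bounding-rectangle area
        (the base of the bone is broad); 'low'/'high' force an end of the
        provisional axis.
    """

    n_slices: int = 50
    slice_thickness_frac: float = 0.0025
    n_lines: int = 7
    projection_tol_frac: float = 0.04
    mbr_band: tuple[float, float] = (0.1500, 0.1525)
    end_frac: float = 0.10
    hull_centroid_mode: str = "volume"
    proximal_end: str = "auto"

    def __post_init__(self) -> None:
        for name in ("slice_thickness_frac", "projection_tol_frac", "end_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        lo, hi = self.mbr_band
        if not (0 < lo < hi < 1):
            raise ValueError(f"mbr_band must satisfy 0 < lo < hi < 1, got {self.mbr_band}")
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.hull_centroid_mode not in ("volume", "vertices"):
            raise ValueError("hull_centroid_mode must be 'volume' or 'vertices'")
        if self.proximal_end not in ("auto", "low", "high"):
            raise ValueError("proximal_end must be 'auto', 'low' or 'high'")

    @property
    def n_landmarks(self) -> int:
        """Total semilandmarks: (2*n_lines + 2) per slice plus the two tips."""
        return self.n_slices * (2 * self.n_lines + 2) + 2
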