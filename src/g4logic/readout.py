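"""Colorimetric readout: released G-quadruplex -> absorbance at 650 nm -> bit.

The released G-rich strand folds into a G-quadruplex that, with hemin,
catalyzes oxidation of TMB by H2O2; the solution turns from colorless to
blue and is read at 650 nm.  The platform defines a single decision
threshold: absorbance strictly above 0.1 reads "1" (true, blue), otherwise
"0" (false, colorless).

The dose-response is modeled linearly between a background and a saturating
absorbance -- no dose-response curve exists for the chemistry beyond its two
endpoint states, and the truth-table logic only requires that fraction 0
and fraction 1 fall unambiguously on either side of the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ReadoutConfig:
    """Parameters of the TMB/H2O2 colorimetric readout.

    wavelength_nm: readout wavelength (informational; fixed at 650 nm).
    threshold:     decision threshold in absorbance units (0.1); outputs are
                   1 only *strictly above* it.
    a_background:  absorbance with no released G4 (residual TMB oxidation).
    a_max:         absorbance at full release.
    hemin/tmb/h2o2_present: cofactor flags -- all three are required for any
                   signal above background.
    """

    wavelength_nm: float = 650.0
    threshold: float = 0.1
    a_background: float = 0.02
    a_max: float = 1.0
    hemin_present: bool = True
    tmb_present: bool = True
    h2o2_present: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_background < self.threshold < self.a_max):
            raise ValueError(
                "readout config requires 0 <= a_background < threshold < a_max"
            )

    @property
    def min_fraction_for_true(self) -> float:
        """Smallest released fraction mapping to output 1 (closed form of
        the linear model)."""
        return (self.threshold - self.a_background) / (
            self.a_max - self.a_background
        )


@dataclass(frozen=True)
class ReadoutResult:
    fraction_released: float
    a650: float
    output_bit: int
    color: str  # "colorless" | "blue"


def absorbance650(fraction_released: float, cfg: ReadoutConfig | None = None
                  ) -> float:
    """Absorbance at 650 nm for a given released-G4 fraction.

    Linear in the released fraction; collapses to background if any of
    hemin, TMB or H2O2 is missing (the catalytic readout cannot proceed).
    """
    cfg = cfg or ReadoutConfig()
    if not (0.0 <= fraction_released <= 1.0):
        raise ValueError(
            f"fraction_released must lie in [0, 1], got {fraction_released}"
        )
    if not (cfg.hemin_present and cfg.tmb_present and cfg.h2o2_present):
        return cfg.a_background
    return cfg.a_background + (cfg.a_max - cfg.a_background) * fraction_released


def binarize(a650: float, cfg: ReadoutConfig | None = None) -> tuple[int, str]:
    """Binarize an absorbance: 1/"blue" iff strictly above the threshold.

    Equality at the threshold reads 0 (the platform's rule is "higher
    than" the threshold).  Negative absorbances are rejected.
    """
    cfg = cfg or ReadoutConfig()
    if a650 < 0:
        raise ValueError(f"absorbance must be non-negative, got {a650}")
    if a650 > cfg.threshold:
        return 1, "blue"
    return 0, "colorless"


def read_fraction(fraction_released: float,
                  cfg: ReadoutConfig | None = None) -> ReadoutResult:
    """Full readout pipeline: fraction -> A650 -> (bit, color)."""
    cfg = cfg or ReadoutConfig()
    a = absorbance650(fraction_released, cfg)
    bit, color = binarize(a, cfg)
    return ReadoutResult(
        fraction_released=fraction_released, a650=a, output_bit=bit,
        color=color,
    )
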