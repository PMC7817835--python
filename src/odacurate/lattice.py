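"""Axial lattice of binding sites along a decorated filament.

Doublet microtubules present one tubulin-dimer binding site every 8 nm
(82 Å) along the axis; the outer dynein arm occupies every third site,
giving a functional repeat of 24 nm.  All phase arithmetic downstream
(register unification, neighbor expansion, cluster detection) is driven
by this one object.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LatticeSpec:
    """Axial site lattice.

    Parameters
    ----------
    step_ang:
        Spacing of adjacent binding sites in Å.  Default 82 Å, the length
        of the tubulin alpha/beta-heterodimer.
    repeat_multiplier:
        Number of binding sites per functional repeat (register count).
        Default 3, so the repeat is 246 Å (~24 nm).
    box_px:
        Extraction box side in pixels.  Metadata only; no image-domain
        operation is performed here.
    """

    step_ang: float = 82.0
    repeat_multiplier: int = 3
    box_px: int = 512

    def __post_init__(self) -> None:
        if self.step_ang <= 0:
            raise ValueError(f"step_ang must be positive, got {self.step_ang}")
        if self.repeat_multiplier < 1:
            raise ValueError(
                f"repeat_multiplier must be >= 1, got {self.repeat_multiplier}"
            )
        if self.box_px < 1:
            raise ValueError(f"box_px must be >= 1, got {self.box_px}")

    @property
    def repeat_ang(self) -> float:
        """Functional repeat in Å, defined as exactly r * step (never an
        independent number, so 3 x 82 = 246 Å rather than a literal 240)."""
        return self.repeat_multiplier * self.step_ang
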