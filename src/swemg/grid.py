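"""V-shaped submental electrode patch geometry.

The patch carries 24 circular contacts (5 mm diameter, 12 mm
center-to-center pitch) arranged along the two arms of a V that follows
the mandibular edge.  Sixteen contacts act as working (recording)
electrodes and eight as references.  Channel ordering places the left-arm
working contacts first (channels 0-7, x < 0) and the right-arm contacts
second (channels 8-15, x > 0), which the laterality metrics rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Contact", "ElectrodeGrid", "GridConfigError", "make_grid"]


class GridConfigError(ValueError):
    """Raised for degenerate patch geometry."""


@dataclass(frozen=True)
class Contact:
    contact_id: int
    position: tuple[float, float]  # mm, patch plane; apex of the V at origin
    diameter: float  # mm
    role: str  # "working" | "reference"


@dataclass
class ElectrodeGrid:
    """A set of contacts; ``working`` indexes the recording channels in order."""

    contacts: list[Contact] = field(default_factory=list)

    @property
    def working(self) -> list[Contact]:
        return [c for c in self.contacts if c.role == "working"]

    @property
    def reference(self) -> list[Contact]:
        return [c for c in self.contacts if c.role == "reference"]

    @property
    def n_channels(self) -> int:
        return len(self.working)

    def working_positions(self) -> np.ndarray:
        """(n_working, 2) array of contact centers in mm."""
        return np.array([c.position for c in self.working], dtype=float)

    def min_center_distance(self) -> float:
        pos = np.array([c.position for c in self.contacts], dtype=float)
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        d[np.diag_indices_from(d)] = np.inf
        return float(d.min())

    def validate_patch(self) -> None:
        """Enforce the full submental-patch invariants (24/16/8, equal
        diameters, 12 mm nearest-neighbor pitch)."""
        if len(self.contacts) != 24:
            raise GridConfigError(f"patch must have 24 contacts, got {len(self.contacts)}")
        if len(self.working) != 16:
            raise GridConfigError(f"patch must have 16 working contacts, got {len(self.working)}")
        diam = {c.diameter for c in self.contacts}
        if len(diam) != 1:
            raise GridConfigError(f"all contact diameters must be equal, got {sorted(diam)}")
        if not math.isclose(self.min_center_distance(), 12.0, abs_tol=1e-9):
            raise GridConfigError(
                f"nearest-neighbor pitch must be 12 mm, got {self.min_center_distance():.6f}"
            )


def make_grid(
    pitch_mm: float = 12.0,
    diameter_mm: float = 5.0,
    contacts_per_arm: int = 12,
    working_per_arm: int = 8,
    arm_half_angle_deg: float = 30.0,
) -> ElectrodeGrid:
    """Build the V-shaped patch layout.

    Contacts sit at arc positions ``k * pitch`` (k = 1..contacts_per_arm)
    along two straight arms inclined at ``arm_half_angle_deg`` from the
    vertical, apex at the origin (the chin point).  With the default 30
    degree half-angle the innermost cross-arm pair is also exactly one
    pitch apart, so the nearest-neighbor distance is uniform at 12 mm.
    The ``working_per_arm`` contacts closest to the apex on each arm are
    working electrodes; the outer ones are references.

    Deterministic for fixed parameters.
    """
    if pitch_mm <= 0:
        raise GridConfigError(f"pitch must be positive, got {pitch_mm}")
    if diameter_mm <= 0 or pitch_mm <= diameter_mm:
        raise GridConfigError(f"need pitch > diameter > 0, got pitch={pitch_mm}, diameter={diameter_mm}")
    if contacts_per_arm < 1 or not 0 < working_per_arm <= contacts_per_arm:
        raise GridConfigError("invalid contact counts")

    theta = math.radians(arm_half_angle_deg)
    left_dir = np.array([-math.sin(theta), math.cos(theta)])
    right_dir = np.array([math.sin(theta), math.cos(theta)])

    contacts: list[Contact] = []
    cid = 0
    # working contacts first, left arm then right arm, inner to outer
    for arm_dir in (left_dir, right_dir):
        for k in range(1, working_per_arm + 1):
            x, y = k * pitch_mm * arm_dir
            contacts.append(Contact(cid, (float(x), float(y)), diameter_mm, "working"))
            cid += 1
    for arm_dir in (left_dir, right_dir):
        for k in range(working_per_arm + 1, contacts_per_arm + 1):
            x, y = k * pitch_mm * arm_dir
            contacts.append(Contact(cid, (float(x), float(y)), diameter_mm, "reference"))
            cid += 1

    grid = ElectrodeGrid(contacts)
    if contacts_per_arm == 12 and working_per_arm == 8 and pitch_mm == 12.0:
        grid.validate_patch()
    return grid
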