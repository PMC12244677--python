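"""Muscle and joint degree-of-freedom vocabularies.

The model covers the 13 major superficial muscles of the upper limb and the
7 main joint degrees of freedom (DOF) from shoulder to wrist.  Three index
sets coexist:

* ``CANONICAL_13`` — the muscle list used for feedback-gain tables, with the
  two biceps heads grouped into ``Bi`` and the two triceps heads into ``Tri``.
* ``PLANT_15`` — the musculoskeletal plant's muscle list, where ``Bi`` and
  ``Tri`` are split back into their heads.
* ``DELAY_11`` — the list used by the reflex-delay literature, which treats
  the three deltoid heads as a single ``Delt`` (the heads are approximately
  equidistant from the spinal cord).

Mappings between the three sets are total and explicit; nothing downstream
hard-codes indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field


CANONICAL_13: tuple[str, ...] = (
    "Delt Ant", "Delt Lat", "Delt Post", "Pec", "Bi", "Tri", "Bra",
    "Brd", "PT", "ECR", "ECU", "FCR", "FCU",
)

PLANT_15: tuple[str, ...] = (
    "Delt Ant", "Delt Lat", "Delt Post", "Pec", "Bi Long", "Bi Short",
    "Tri Long", "Tri Lat", "Bra", "Brd", "PT", "ECR", "ECU", "FCR", "FCU",
)

#: canonical muscle -> plant heads
HEAD_MAP: dict[str, tuple[str, ...]] = {
    "Delt Ant": ("Delt Ant",),
    "Delt Lat": ("Delt Lat",),
    "Delt Post": ("Delt Post",),
    "Pec": ("Pec",),
    "Bi": ("Bi Long", "Bi Short"),
    "Tri": ("Tri Long", "Tri Lat"),
    "Bra": ("Bra",),
    "Brd": ("Brd",),
    "PT": ("PT",),
    "ECR": ("ECR",),
    "ECU": ("ECU",),
    "FCR": ("FCR",),
    "FCU": ("FCU",),
}

DELAY_11: tuple[str, ...] = (
    "Delt", "Pec", "Bi", "Tri", "Bra", "Brd", "PT", "ECR", "ECU", "FCR", "FCU",
)

#: canonical muscle -> delay-table muscle (deltoid heads collapsed)
DELAY_MAP: dict[str, str] = {
    m: ("Delt" if m.startswith("Delt") else m) for m in CANONICAL_13
}

DOF_7: tuple[str, ...] = ("SFE", "SAA", "SIER", "EFE", "FPS", "WFE", "WRUD")

DOF_NAMES: dict[str, str] = {
    "SFE": "Shoulder Flexion-Extension",
    "SAA": "Shoulder Abduction-Adduction",
    "SIER": "Shoulder Internal-External Rotation",
    "EFE": "Elbow Flexion-Extension",
    "FPS": "Forearm Pronation-Supination",
    "WFE": "Wrist Flexion-Extension",
    "WRUD": "Wrist Radial-Ulnar Deviation",
}


@dataclass(frozen=True)
class MuscleSet:
    """The three muscle index sets and the mappings between them."""

    canonical_13: tuple[str, ...] = CANONICAL_13
    plant_15: tuple[str, ...] = PLANT_15
    head_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(HEAD_MAP))
    delay_11: tuple[str, ...] = DELAY_11
    delay_map: dict[str, str] = field(default_factory=lambda: dict(DELAY_MAP))

    def __post_init__(self) -> None:
        if len(self.canonical_13) != 13:
            raise ValueError("canonical muscle set must have 13 entries")
        if len(self.plant_15) != 15:
            raise ValueError("plant muscle set must have 15 entries")
        covered = [h for m in self.canonical_13 for h in self.head_map[m]]
        if sorted(covered) != sorted(self.plant_15):
            raise ValueError("head_map must be total and surjective onto plant_15")
        if set(self.delay_map) != set(self.canonical_13):
            raise ValueError("delay_map must cover all canonical muscles")
        if set(self.delay_map.values()) != set(self.delay_11):
            raise ValueError("delay_map must be surjective onto delay_11")

    def heads(self, muscle: str) -> tuple[str, ...]:
        return self.head_map[muscle]

    def canonical_of_head(self, head: str) -> str:
        for m, hs in self.head_map.items():
            if head in hs:
                return m
        raise KeyError(head)


@dataclass(frozen=True)
class DOFSet:
    """Ordered joint degrees of freedom, proximal to distal."""

    dofs: tuple[str, ...] = DOF_7

    def __post_init__(self) -> None:
        if len(self.dofs) != 7:
            raise ValueError("DOF set must have exactly 7 entries")

    def index(self, dof: str) -> int:
        return self.dofs.index(dof)


MUSCLES = MuscleSet()
DOFS = DOFSet()
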