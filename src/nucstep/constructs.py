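"""Nucleosome labeling constructs.

A construct describes where the FRET donor (Cy3) sits on the histone
octamer, where the acceptor (Cy5) sits on (or off) the DNA, whether the
DNA carries a 2-nt single-stranded gap at one of the SHL±2 ATPase
engagement sites, and the initial linker DNA length.  The gap blocks
translocation past that site, which forces the direction of remodeling:
a gap at SHL-2 permits only exit-side movement, a gap at SHL+2 only
entry-side movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DONOR_SITES = ("H2A", "H2B", "H3")
ACCEPTOR_PLACEMENTS = ("end", "backbone", "octamer")
GAPS = ("none", "SHL-2", "SHL+2")


@dataclass(frozen=True)
class ConstructSpec:
    """Labeling scheme and geometry of a mononucleosome substrate.

    Parameters
    ----------
    name
        Identifier, e.g. ``"H2A/[end,+6]"``.
    donor_site
        Histone carrying the Cy3 donor: ``H2A``, ``H2B`` or ``H3``.
    acceptor_placement
        ``end`` (Cy5 at the linker DNA end), ``backbone`` (Cy5 in the
        sugar-phosphate backbone, possibly inside the nucleosome), or
        ``octamer`` (Cy5 on a second histone copy, as in H2A/H2A).
    acceptor_offset_bp
        Signed position of the acceptor relative to the nucleosome edge;
        end labels are outside the wrap (offset >= 0), backbone labels may
        be inside (negative offset).
    gap
        Position of a 2-nt ssDNA gap, if any.
    initial_linker_bp
        Linker DNA length between the nucleosome edge and the acceptor.
    movement_bias
        Probability that a simulated enzyme engagement produces
        entry-side movement (ignored when a gap fixes the direction).
    """

    name: str
    donor_site: str
    acceptor_placement: str
    acceptor_offset_bp: int = 0
    gap: str = "none"
    initial_linker_bp: int = 0
    movement_bias: float = 0.5

    def __post_init__(self) -> None:
        if self.donor_site not in DONOR_SITES:
            raise ValueError(f"unknown donor site {self.donor_site!r}")
        if self.acceptor_placement not in ACCEPTOR_PLACEMENTS:
            raise ValueError(
                f"unknown acceptor placement {self.acceptor_placement!r}"
            )
        if self.gap not in GAPS:
            raise ValueError(f"unknown gap {self.gap!r}")
        if self.acceptor_placement == "end" and self.acceptor_offset_bp < 0:
            raise ValueError("end labels sit outside the nucleosome (offset >= 0)")
        if not 0.0 <= self.movement_bias <= 1.0:
            raise ValueError("movement_bias must lie in [0, 1]")
        if self.initial_linker_bp < 0:
            raise ValueError("initial_linker_bp must be non-negative")

    @property
    def dna_labeled(self) -> bool:
        return self.acceptor_placement in ("end", "backbone")

    @property
    def inverted_classification(self) -> bool:
        """True when a FRET rise signals *exit*-side movement.

        For end-labeled constructs the labeled DNA end moving into the
        nucleosome (entry-side) raises FRET.  When the acceptor sits on
        the backbone inside the nucleosome (negative offset, e.g.
        H2A/[backbone,-15]) the mapping inverts: exit-side movement first
        brings the internal label toward the edge, raising FRET.
        """
        return self.acceptor_placement == "backbone" and self.acceptor_offset_bp < 0

    def forced_movement(self) -> str | None:
        """Movement class imposed by an ssDNA gap, or None."""
        if self.gap == "SHL-2":
            return "exit"
        if self.gap == "SHL+2":
            return "entry"
        return None


def _std(name: str, donor: str, placement: str, offset: int, linker: int,
         gap: str = "none") -> ConstructSpec:
    return ConstructSpec(
        name=name, donor_site=donor, acceptor_placement=placement,
        acceptor_offset_bp=offset, gap=gap, initial_linker_bp=linker,
    )


#: Constructs used throughout the study, keyed by name.
STANDARD_CONSTRUCTS: dict[str, ConstructSpec] = {
    c.name: c
    for c in (
        _std("H2A/[end,+6]", "H2A", "end", 6, 6),
        _std("H3/[end,+6]", "H3", "end", 6, 6),
        _std("H2A/[backbone,+6]", "H2A", "backbone", 6, 6),
        _std("H2A/[end,+11]", "H2A", "end", 11, 11),
        _std("H2A/[end,+12]", "H2A", "end", 12, 12),
        _std("H3/[end,+9]", "H3", "end", 9, 9),
        ConstructSpec("H2A/[backbone,-15]", "H2A", "backbone", -15, "none", 0),
        ConstructSpec("H2A/H2A", "H2A", "octamer"),
        ConstructSpec("H2B/H2B", "H2B", "octamer"),
    )
}


def get_construct(name: str) -> ConstructSpec:
    try:
        return STANDARD_CONSTRUCTS[name]
    except KeyError:
        raise KeyError(
            f"unknown construct {name!r}; known: {sorted(STANDARD_CONSTRUCTS)}"
        ) from None


def with_gap(construct: ConstructSpec, gap: str) -> ConstructSpec:
    """Copy of *construct* with a ssDNA gap installed."""
    return ConstructSpec(
        name=f"{construct.name} gap={gap}",
        donor_site=construct.donor_site,
        acceptor_placement=construct.acceptor_placement,
        acceptor_offset_bp=construct.acceptor_offset_bp,
        gap=gap,
        initial_linker_bp=construct.initial_linker_bp,
        movement_bias=construct.movement_bias,
    )
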