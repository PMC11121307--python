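"""Membrane composition bookkeeping: lipid class percentages, charge balance.

The simulated systems embed the protein in an inner-bacterial-membrane
mimic of phosphatidylethanolamine (PE) and cardiolipin (CL) species; this
module validates and summarizes that metadata.  No coordinates are built
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Formal charge per lipid class (cardiolipin modeled fully deprotonated).
DEFAULT_CLASS_CHARGES = {"PE": 0, "CL": -2}

#: Formal charge per ion species.
DEFAULT_ION_CHARGES = {"K": +1, "CL-": -1, "NA": +1}


@dataclass
class MembraneComposition:
    """Lipid species counts with class assignments, plus solvent and salt."""

    species_counts: dict[str, int]
    class_map: dict[str, str]
    waters: int = 0
    salt_mM: float = 0.0
    class_charges: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_CHARGES)
    )

    def __post_init__(self):
        for species, count in self.species_counts.items():
            if not isinstance(count, int) or count <= 0:
                raise ValidationError(
                    f"count for {species!r} must be a positive integer, got {count}"
                )
        unmapped = set(self.species_counts) - set(self.class_map)
        if unmapped:
            raise ValidationError(
                f"species with no lipid class: {sorted(unmapped)}"
            )

    def total_lipids(self) -> int:
        return sum(self.species_counts.values())

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for species, count in self.species_counts.items():
            cls = self.class_map[species]
            out[cls] = out.get(cls, 0) + count
        return out

    def lipid_charge(self) -> int:
        return sum(
            count * self.class_charges.get(self.class_map[species], 0)
            for species, count in self.species_counts.items()
        )


def largest_remainder_percentages(counts: dict[str, int]) -> dict[str, int]:
    """Integer percentages that sum to exactly 100 (largest-remainder rule).

    Exact shares are floored, then the leftover points go to the classes
    with the largest fractional remainders (ties broken by class name), which
    reproduces conventional printed splits such as 73/27 from 73.43/26.57.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError("total count must be positive")
    exact = {k: 100.0 * v / total for k, v in counts.items()}
    floors = {k: int(exact[k]) for k in counts}
    leftover = 100 - sum(floors.values())
    remainders = sorted(
        counts, key=lambda k: (-(exact[k] - floors[k]), k)
    )
    for k in remainders[:leftover]:
        floors[k] += 1
    return floors


def class_percentages(comp: MembraneComposition) -> dict[str, int]:
    """Per-class share of all lipid molecules, as reconciled integer percent."""
    return largest_remainder_percentages(comp.class_counts())


def net_charge_check(
    comp: MembraneComposition,
    ion_counts: dict[str, int],
    protein_charge: int = 0,
    ion_charges: dict[str, int] | None = None,
) -> int:
    """Residual system charge: lipids + ions + protein.  Zero means neutral."""
    charges = dict(DEFAULT_ION_CHARGES)
    if ion_charges:
        charges.update(ion_charges)
    unknown = set(ion_counts) - set(charges)
    if unknown:
        raise ValidationError(f"ions with no configured charge: {sorted(unknown)}")
    ion_charge = sum(charges[ion] * n for ion, n in ion_counts.items())
    return comp.lipid_charge() + ion_charge + protein_charge


def reference_membrane_composition() -> MembraneComposition:
    """The PE/CL inner-membrane mimic used by the simulated systems.

    Five lipid species: three PE (DYPE, DPPE, PMPE) and two dianionic
    cardiolipins (PMCL, TYCL), solvated with TIP3P water at 150 mM KCl.
    """
    return MembraneComposition(
        species_counts={
            "DYPE": 206,
            "DPPE": 96,
            "PMPE": 96,
            "PMCL": 108,
            "TYCL": 36,
        },
        class_map={
            "DYPE": "PE",
            "DPPE": "PE",
            "PMPE": "PE",
            "PMCL": "CL",
            "TYCL": "CL",
        },
        waters=36785,
        salt_mM=150.0,
    )
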