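#!/usr/bin/env python
"""Validate the membrane composition metadata of the simulated systems.

Checks the PE/CL class split of the five-species inner-membrane mimic and
the charge balance against the potassium counter-ions.
"""

import json
from pathlib import Path

from halfchannel.membrane import (
    class_percentages,
    net_charge_check,
    reference_membrane_composition,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    comp = reference_membrane_composition()
    pct = class_percentages(comp)
    residual = net_charge_check(comp, {"K": 288})
    payload = {
        "species_counts": comp.species_counts,
        "total_lipids": comp.total_lipids(),
        "class_percentages": pct,
        "lipid_charge_e": comp.lipid_charge(),
        "residual_charge_with_288_K": residual,
        "waters": comp.waters,
        "salt_mM": comp.salt_mM,
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    out = results / "membrane_composition.json"
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    print(f"{comp.total_lipids()} lipids -> {pct['PE']}% PE / {pct['CL']}% CL")
    print(f"lipid charge {comp.lipid_charge()} e; with 288 K+: residual "
          f"{residual} e")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
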