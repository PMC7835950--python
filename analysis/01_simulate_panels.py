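"""Generate the synthetic assay panels used by the downstream analyses.

Writes one tidy rate-table CSV per preparation × substrate preset (cardiac and
hepatic, OG and OA), each covering the three phosphonate inhibitors at their
default dose grids with 3% multiplicative noise and 3 replicates, plus a
provenance JSON recording the generating configuration and seed.
"""

import json
from pathlib import Path

from oxokinetics.io import write_panel_csv
from oxokinetics.simulate import heart_liver_presets, simulate_inhibition_panel

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "panels"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, config in heart_liver_presets().items():
        panel = simulate_inhibition_panel(config, seed=SEED)
        series_list = [s for by in panel.values() for s in by.values()]
        write_panel_csv(series_list, OUT / f"{name}_panel.csv")
        prov = json.loads(config.to_json())
        prov["seed"] = SEED
        (OUT / f"{name}_panel.provenance.json").write_text(
            json.dumps(prov, indent=2)
        )
        n_points = sum(len(s) for s in series_list)
        print(f"{name}: {len(series_list)} series, {n_points} rate measurements")


if __name__ == "__main__":
    main()
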