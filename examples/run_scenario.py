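"""Run the packaged telogen_vs_anagen scenario end to end.

Simulates every module, analyzes, and writes CSV inputs plus report.json and
manifest.json into ./scenario_out (seeds recorded in the manifest).
"""

import json
from importlib import resources

from follipulse.scenario import run_scenario

path = resources.files("follipulse") / "scenarios" / "telogen_vs_anagen.yaml"
report = run_scenario(str(path), "scenario_out")
print(json.dumps(report["results"]["volume"]["contraction_fractions_pct"], indent=2))
print("full report in scenario_out/report.json")
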