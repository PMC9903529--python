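"""Run the end-to-end pipeline and list what it writes.

simulate -> exclusions -> compositional descriptives -> two cross-lagged
models -> mediation -> reallocation curves -> manifest.  Everything is
plain CSV/JSON and fully reproducible from the seed.
"""

import json

from movecoda.pipeline import RunConfig, run_pipeline

out = run_pipeline(RunConfig(out_dir="scratch/example_run", n=231, seed=42))
print("run directory:", out)
for path in sorted(out.iterdir()):
    print("  ", path.name)

report = json.loads((out / "exclusion_report.json").read_text())
print("\nroster", report["initial_n"], "->", report["final_n"], "analytical")

body = json.loads((out / "clpm_bodycomp.json").read_text())
print("body-composition model: chi2 = %.2f on %d df (CFI %.3f)" % (
    body["chi2"], body["df"], body["fit_indices"]["cfi"]))
# Re-running with the same seed reproduces byte-identical reports; the
# manifest records the seed and a configuration hash for traceability.
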