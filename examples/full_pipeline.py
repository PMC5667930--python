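"""End-to-end run: generate -> filter -> debias -> score -> tag -> report.

Writes all intermediates to a run directory and prints the headline
comparison: primary-emotion probabilities in the debiased (bot-free) corpus
versus the biased corpus (humans + bots). Debiasing should raise the joy
share, since bots post predominantly negative spam.
"""

import json
import tempfile
from pathlib import Path

from hookahsent import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "run"
    provenance = run_pipeline(PipelineConfig(seed=3), out)

    for stage in provenance["stages"]:
        print(f"{stage['stage']:>16}: {stage['n_in']:6d} -> {stage['n_out']:6d}")

    debiased = json.loads((out / "summary_debiased.json").read_text())
    biased = json.loads((out / "summary_biased.json").read_text())
    print("\nlabel percentages (debiased):", debiased["label_pcts"])
    print("label percentages (biased):  ", biased["label_pcts"])
    print("\njoy probability: debiased "
          f"{debiased['primary_probs']['joy']}% vs biased "
          f"{biased['primary_probs']['joy']}%")
    print((out / "comparison.csv").read_text())
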