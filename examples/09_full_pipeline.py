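"""The whole pipeline end to end from one config, equivalent to `lncweave run`.

Every stage reads and writes files in the output directory, so each stage
can also be re-run on its own (`lncweave coexpress --outdir out ...`).
"""

import json

from lncweave.pipeline import PipelineConfig, run_pipeline
from lncweave.synthetic_data import SimulationConfig

cfg = PipelineConfig(outdir="lncweave_demo_out", seed=1, simulate=SimulationConfig(seed=1))
manifest = run_pipeline(cfg)

print(json.dumps(manifest["stages"], indent=2))
print(f"\noutputs in {cfg.outdir}/ (network.tsv, sponge_triplets.tsv, "
      "shared_tfbs.tsv, enrichment.tsv, ... plus truth_*.tsv ground truth)")
# Identical seed + config reproduce every output byte for byte.
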