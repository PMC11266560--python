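"""End-to-end pipeline run with the shipped default configuration.

Writes all stage outputs and the provenance manifest under results/pipeline/.
"""

import json
import sys
from pathlib import Path

import yaml

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from leaflet_smlm import run_pipeline
from leaflet_smlm.pipeline import load_config

RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    cfg = load_config(ROOT / "configs" / "default.yaml")
    manifest = run_pipeline(cfg, output_dir=RESULTS / "pipeline")
    print(json.dumps(manifest["report"], indent=2))


if __name__ == "__main__":
    main()
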