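"""One-call pipeline run from a config, writing every artifact plus a report.

Equivalent to `tdufe run-all --config cfg.yaml` from the shell.
"""

import json
import tempfile
from pathlib import Path

from tdufe import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as d:
    cfg = RunConfig(
        input_mode="synthetic",
        synthetic={"n_features": 2000, "n_signal": 100, "effect_size": 6.0},
        threshold=0.01,
        output_dir=str(Path(d) / "run"),
        seed=42,
    )
    report = run_pipeline(cfg)
    print("headline counts:", json.dumps(report["counts"]))
    print("factor choice:", json.dumps(report["factor_choice"]))
    print(f"config hash: {report['config_hash']} (changes iff an effective setting changes)")
    print("artifacts written:", sorted(p.name for p in (Path(d) / "run").iterdir()))
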