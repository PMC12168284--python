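"""Run the complete configured pipeline end to end.

Equivalent to `plaquestab all -c examples/demo_config.yaml -o demo_out`.
Every stage writes its artifacts plus a manifest; rerunning with the same
config and seed reproduces everything bit-identically.
"""

from pathlib import Path

import plaquestab as ps

config = ps.load_config(Path(__file__).parent / "demo_config.yaml")
ctx = ps.run_pipeline(config, "demo_out")

print(Path("demo_out/report/report.md").read_text())
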