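"""One-call demo pipeline: simulate, model, derive CCIs, classify, report.

Equivalent to ``auriclass run --seed 5 --out demo_run`` on the command
line.  All outputs are plain CSV/JSON; reruns with the same seed are
byte-identical.
"""

import auriclass as ac

config = ac.PipelineConfig(n_subjects=30, seed=5)
out = ac.run_pipeline(config, "demo_run")
print(ac.make_report(out))
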