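"""Parameter-recovery scoreboard for the whole analysis.

Three simulation studies: (1) type-I calibration of the s(age) test on null
cohorts, (2) power under a linear aging trend, (3) end-to-end recovery of
the injected amplitude/connectivity aging pattern through the full imaging
pipeline.  Prints a PASS/FAIL scoreboard and exits nonzero on failure.
"""

import json
import sys
from pathlib import Path

from csa_aging.pipeline import validate_recovery

board = validate_recovery(seed=2024, n_typeI=200, n_power=50, n_e2e=25)

out = Path("results/recovery_scoreboard.json")
out.parent.mkdir(parents=True, exist_ok=True)
out.write_text(json.dumps(board, indent=2) + "\n")
print(f"scoreboard written to {out}")
sys.exit(0 if board["passed"] else 1)
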