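"""Shared configuration for the numbered analysis scripts.

All scripts use the same validated default design and master seed, and
write their outputs under results/ next to the repository root.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from volecall.pipeline import validate_config  # noqa: E402

RESULTS = ROOT / "results"
CONFIG = validate_config({})          # default design, seed 20190226
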