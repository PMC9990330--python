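"""Shared paths and study-design constants for the analysis drivers.

Bulky intermediates (fix tables, the used/available design) live under
scratch/; small tables and fitted summaries under results/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SCRATCH.mkdir(exist_ok=True)
RESULTS.mkdir(exist_ok=True)

#: master seed of the worked analysis
SEED = 1

#: tag deployments: 12 individuals, one non-breeding deployment each, with
#: matching breeding-season data for the home-range comparisons
N_INDIVIDUALS = 12
WEEKS_NON_BREEDING = 26
WEEKS_BREEDING = 16
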