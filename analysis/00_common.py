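"""Shared run configuration for the numbered analysis scripts.

One landscape is simulated once (01) into scratch/run and every later
script re-reads it from disk, so each step is reproducible in isolation.
Raw tables live under scratch/ (they are bulky); the small derived
tables each script produces are copied into results/.
"""

from pathlib import Path
import shutil
import sys

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from topophen.config import RunConfig, SyntheticConfig  # noqa: E402

RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"

# the study layout: 5 sites (4 core + 1 extra) x paired aspects x 3 plots,
# four spring seasons, weekly surveys
CONFIG = RunConfig(
    synthetic=SyntheticConfig(seed=1, n_sites=5),
    outdir=RUN_DIR,
    overwrite=True,
    verbosity=0,
)


def publish(*names: str) -> None:
    """Copy small derived tables from the run directory into results/."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        src = RUN_DIR / name
        shutil.copy(src, RESULTS / Path(name).name)
        print(f"  -> results/{Path(name).name}")
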