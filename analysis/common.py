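"""Shared paths and the default study scenario for the analysis scripts."""

from pathlib import Path

from asnmd.synthetic_data import ScenarioConfig, build_scenario, write_scenario

ROOT = Path(__file__).resolve().parents[1]
SCENARIO_DIR = ROOT / "scratch" / "scenario"
RESULTS = ROOT / "results"

# The study conditions: 200 genes, 10 poison + 10 essential negative feedback
# loops, 20 null (self-binding but effect-free) RBPs, phi0 = 0.5, |delta| = 0.3,
# junction depth 200, expression-confound slope 0.01 per decade of fold change.
STUDY_SEED = 101
STUDY_CONFIG = ScenarioConfig(seed=STUDY_SEED)


def ensure_scenario() -> Path:
    """Build and write the default scenario if it is not on disk yet."""
    if not (SCENARIO_DIR / "manifest.json").exists():
        SCENARIO_DIR.parent.mkdir(parents=True, exist_ok=True)
        write_scenario(build_scenario(STUDY_CONFIG), SCENARIO_DIR, force=True)
    RESULTS.mkdir(exist_ok=True)
    return SCENARIO_DIR
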