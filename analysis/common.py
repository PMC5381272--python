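"""Shared plumbing for the numbered analysis drivers: one seed, one output
directory, one cached pipeline invocation per stage set."""

from pathlib import Path

from glycoclam.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1

SCRATCH.mkdir(exist_ok=True)


def get_results(stages):
    """Run the pipeline (simulate plus the requested stages) at the default
    study conditions."""
    stages = tuple(dict.fromkeys(("simulate",) + tuple(stages)))
    return run_pipeline(stages=stages, outdir=RESULTS, seed=SEED)
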