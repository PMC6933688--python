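"""Shared setup for the analysis drivers: one seeded desk-scale study."""

from pathlib import Path

from herdimpute import benchmark

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

_study = None


def get_study():
    global _study
    if _study is None:
        print(f"building desk-scale study (seed={SEED}) ...")
        _study = benchmark.build_study(seed=SEED)
    return _study


def outpath(name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS / name
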