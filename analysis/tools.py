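"""Shared constants for the analysis drivers: the reduced reference
geometry on which all parametric studies run, and a helper for writing
sweep summaries."""

from pathlib import Path

from osteoadapt.geometry import GeometryParams

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: Reference configuration: ~3,100 elements, fast enough to run every
#: sweep value for the full 80-iteration budget on one CPU.
REFERENCE_GEOMETRY = GeometryParams(element_size=0.6)


def save_summary(result, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{result.parameter}_summary.csv"
    result.summary.to_csv(path, index=False, float_format="%.10g")
    return path
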