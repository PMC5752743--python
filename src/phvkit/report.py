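"""Report writing: deterministic CSV tables plus a JSON run manifest.

Table layout mirrors a validation study's summary battery: ``table1``/
``table2`` are boys'/girls' summaries by chronological-age group,
``table3``/``table4`` the same by years relative to PHV, ``table5``/
``table6`` the +/-0.5-year hit-rate tables by CA group and PHV bin,
``ba_ca``/``ba_phv`` the Bland-Altman fits, and ``spread`` the
intra-individual ranges. Numbers are written to 2 decimals (internal
computation is full precision); reruns with the same seed produce
byte-identical tables. The manifest additionally carries a timestamp, so it
is identical across reruns except for that field.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, RunManifest, config_hash
from .validation import ValidationReport

__all__ = ["write_report", "read_table"]


def _csv_bytes(df: pd.DataFrame, decimals: int = 2) -> str:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(decimals)
    buf = io.StringIO()
    out.to_csv(buf, index=False, float_format=f"%.{decimals}f",
               lineterminator="\n")
    return buf.getvalue()


def write_report(
    report: ValidationReport,
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the full table set and manifest; returns ``{name: path}``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or PipelineConfig()

    tables: dict[str, pd.DataFrame] = {
        "table1": report.ca_tables.get("M", pd.DataFrame()),
        "table2": report.ca_tables.get("F", pd.DataFrame()),
        "table3": report.phv_tables.get("M", pd.DataFrame()),
        "table4": report.phv_tables.get("F", pd.DataFrame()),
        "table5": report.hit_rate_ca,
        "table6": report.hit_rate_phv,
        "ba_ca": report.ba_ca,
        "ba_phv": report.ba_phv,
        "spread": report.spread,
        "fits": report.fits,
    }
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        p.write_text(_csv_bytes(df if df is not None else pd.DataFrame()))
        paths[name] = p

    counts = (
        report.visits.drop_duplicates("subject_id")
        .groupby(["sex", "maturity_class"])
        .size()
        .to_dict()
    )
    manifest = RunManifest(
        seed=int(seed if seed is not None else cfg.cohort.seed),
        config_hash=config_hash(cfg),
        version=__version__,
        n_boys=int((report.fits["sex"] == "M").sum()),
        n_girls=int((report.fits["sex"] == "F").sum()),
        class_counts={f"{s}_{c}": int(n) for (s, c), n in sorted(counts.items())},
        exclusions=report.exclusions,
    ).finalize()
    mp = outdir / "manifest.json"
    mp.write_text(manifest.to_json() + "\n")
    paths["manifest"] = mp
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the report CSVs."""
    return pd.read_csv(path)
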