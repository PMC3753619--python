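"""File formats: melting-trace CSV/TSV, FASTA registries, motif BED/TSV,
fit JSON and the summary/comparison tables.

Column names and units are documented in docs/formats.md. Temperatures are
°C, energies kJ/mol, entropies J/(K mol) in every file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .analysis import MeltCurve, VantHoffFit, split_ramps
from .compare import ComparisonResult, ThermoSummary, Uncertain
from .exceptions import ValidationError
from .oligo import MotifHit, Oligo, OligoRegistry
from .thermo import ThermoParams

TRACE_COLUMNS = ("temperature_C", "signal")
SUMMARY_COLUMNS = (
    "pair", "pH", "n",
    "Tm_C", "Tm_sd",
    "dH_kJ_mol", "dH_sd",
    "dS_J_K_mol", "dS_sd",
    "dG_kJ_mol", "dG_sd",
)
COMPARISON_COLUMNS = (
    "construct", "reference", "pH",
    "ddG_kJ_mol", "ddG_sd",
    "dTm_C", "dTm_sd",
    "rel_destab_pct", "rel_destab_sd",
    "p_adj", "stars",
)


# -- melting traces ---------------------------------------------------


def write_trace(path, curves: Iterable[MeltCurve]) -> None:
    """Write curves to one delimited file (columns per docs/formats.md)."""
    frames = []
    for c in curves:
        df = pd.DataFrame(
            {"temperature_C": c.temperature_c, "signal": c.signal}
        )
        df["channel"] = c.channel
        df["ramp"] = c.meta.get("ramp_index", 0)
        df["replicate"] = c.meta.get("replicate", 0)
        if "pair" in c.meta:
            df["pair"] = c.meta["pair"]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace(path, channel: str | None = None, meta: dict | None = None) -> list[MeltCurve]:
    """Read a delimited trace file into per-ramp curves.

    Requires ``temperature_C`` and ``signal`` columns (tab or comma
    separated); optional ``ramp``, ``replicate``, ``channel`` and ``pair``
    columns partition the file, otherwise direction reversals do.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # malformed/empty file
        raise ValidationError(f"{path}: cannot parse trace file ({exc})") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if channel is not None and "channel" in df.columns:
        df = df[df["channel"] == channel]
    if df.empty:
        raise ValidationError(f"{path}: no data rows")

    group_cols = [c for c in ("pair", "replicate", "channel", "ramp") if c in df.columns]
    curves: list[MeltCurve] = []
    groups = df.groupby(group_cols, sort=False) if group_cols else [((), df)]
    for key, sub in groups:
        m = dict(meta or {})
        m.update(dict(zip(group_cols, np.atleast_1d(key))))
        ch = str(m.pop("channel", channel or "A260"))
        ramp = m.pop("ramp", None)
        if ramp is not None:
            m["ramp_index"] = int(ramp)
        if "replicate" in m:
            m["replicate"] = int(m["replicate"])
        t = sub["temperature_C"].to_numpy(dtype=float)
        s = sub["signal"].to_numpy(dtype=float)
        d = np.diff(t)
        if np.all(d > 0) or np.all(d < 0):
            direction = "heating" if t[-1] > t[0] else "cooling"
            curves.append(MeltCurve(t, s, channel=ch, ramp_direction=direction, meta=m))
        else:  # a whole protocol in one block: split at reversals
            curves.extend(split_ramps(t, s, channel=ch, meta=m))
    return curves


# -- oligo registries -------------------------------------------------


def read_oligos(path) -> OligoRegistry:
    """Read oligos from FASTA, or from name<TAB>sequence / plain lines."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from io import StringIO

        records = list(SeqIO.parse(StringIO(text), "fasta"))
        return OligoRegistry(Oligo(r.id, str(r.seq)) for r in records)
    reg = OligoRegistry()
    for i, line in enumerate(filter(None, map(str.strip, text.splitlines()))):
        parts = line.split()
        if len(parts) == 1:
            reg.add(Oligo(f"seq{i + 1}", parts[0]))
        else:
            reg.add(Oligo(parts[0], parts[1]))
    return reg


def write_oligos_fasta(path, oligos: Iterable[Oligo]) -> None:
    records = [
        SeqRecord(Seq(o.sequence), id=o.name, description="") for o in oligos
    ]
    SeqIO.write(records, str(path), "fasta")


# -- motif hits -------------------------------------------------------


def write_hits_bed(path, hits: Sequence[tuple[str, MotifHit]]) -> None:
    """BED6-style motif output: 0-based half-open, chrom = oligo name."""
    with open(path, "w") as fh:
        for name, hit in hits:
            fh.write(
                f"{name}\t{hit.start}\t{hit.end}\t{hit.motif_class}\t0\t+\n"
            )


def hits_to_frame(hits: Sequence[tuple[str, MotifHit]]) -> pd.DataFrame:
    """Human-readable table with 1-based inclusive coordinates."""
    rows = [
        {
            "oligo": name,
            "motif": hit.motif_class,
            "start_1based": hit.start + 1,
            "end_1based": hit.end,
            "n_runs": len(hit.runs),
            "run_lengths": ",".join(str(l) for _, l in hit.runs),
            "loop_lengths": ",".join(str(l) for l in hit.loop_lengths),
        }
        for name, hit in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "oligo", "motif", "start_1based", "end_1based",
            "n_runs", "run_lengths", "loop_lengths",
        ],
    )


# -- fits and summaries ----------------------------------------------


def fit_to_dict(fit: VantHoffFit) -> dict:
    return {
        "delta_H_kJ_mol": fit.params.delta_H,
        "delta_S_J_K_mol": fit.params.delta_S,
        "molecularity": fit.params.molecularity.value,
        "c_total_M": fit.params.c_total,
        "Tm_obs_C": fit.tm_obs_c,
        "Tm_deriv_C": fit.tm_deriv_c,
        "dG_std_kJ_mol": fit.delta_G_std,
        "r_squared": fit.r_squared,
        "theta_window": list(fit.theta_window),
        "n_points_used": fit.n_points_used,
        "meta": {k: v for k, v in fit.meta.items()},
    }


def write_fit_json(path, fits: Sequence[VantHoffFit]) -> None:
    with open(path, "w") as fh:
        json.dump([fit_to_dict(f) for f in fits], fh, indent=1)


def read_fit_json(path) -> list[VantHoffFit]:
    with open(path) as fh:
        raw = json.load(fh)
    fits = []
    for d in raw:
        params = ThermoParams(
            d["delta_H_kJ_mol"], d["delta_S_J_K_mol"],
            d["molecularity"], d.get("c_total_M"),
        )
        fits.append(
            VantHoffFit(
                params=params,
                tm_obs_c=d["Tm_obs_C"],
                tm_deriv_c=d["Tm_deriv_C"],
                delta_G_std=d["dG_std_kJ_mol"],
                r_squared=d["r_squared"],
                theta_window=tuple(d["theta_window"]),
                n_points_used=d["n_points_used"],
                meta=d.get("meta", {}),
            )
        )
    return fits


def summaries_to_frame(summaries: Iterable[ThermoSummary]) -> pd.DataFrame:
    rows = [
        {
            "pair": s.pair, "pH": s.ph, "n": s.n,
            "Tm_C": s.tm_c.value, "Tm_sd": s.tm_c.sigma,
            "dH_kJ_mol": s.delta_H.value, "dH_sd": s.delta_H.sigma,
            "dS_J_K_mol": s.delta_S.value, "dS_sd": s.delta_S.sigma,
            "dG_kJ_mol": s.delta_G.value, "dG_sd": s.delta_G.sigma,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def write_summary_tsv(path, summaries: Iterable[ThermoSummary]) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False)


def read_summary_tsv(path) -> dict[str, ThermoSummary]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: summary is missing columns {missing}")
    out = {}
    for _, r in df.iterrows():
        out[r["pair"]] = ThermoSummary(
            pair=r["pair"], ph=float(r["pH"]), n=int(r["n"]),
            tm_c=Uncertain(r["Tm_C"], r["Tm_sd"]),
            delta_H=Uncertain(r["dH_kJ_mol"], r["dH_sd"]),
            delta_S=Uncertain(r["dS_J_K_mol"], r["dS_sd"]),
            delta_G=Uncertain(r["dG_kJ_mol"], r["dG_sd"]),
        )
    return out


def comparisons_to_frame(
    results: Sequence[ComparisonResult], ph_by_construct: dict | None = None
) -> pd.DataFrame:
    ph_by_construct = ph_by_construct or {}
    rows = []
    for r in results:
        rows.append(
            {
                "construct": r.construct,
                "reference": r.reference,
                "pH": ph_by_construct.get(r.construct, float("nan")),
                "ddG_kJ_mol": r.ddg.value, "ddG_sd": r.ddg.sigma,
                "dTm_C": r.dtm.value, "dTm_sd": r.dtm.sigma,
                "rel_destab_pct": r.rel_destab.value if r.rel_destab else float("nan"),
                "rel_destab_sd": r.rel_destab.sigma if r.rel_destab else float("nan"),
                "p_adj": r.p_adj if r.p_adj is not None else float("nan"),
                "stars": r.stars if r.stars is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=list(COMPARISON_COLUMNS))


def write_comparison_tsv(path, results, ph_by_construct=None) -> None:
    comparisons_to_frame(results, ph_by_construct).to_csv(path, sep="\t", index=False)
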