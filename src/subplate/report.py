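"""Aggregation into pairwise matrices, group comparisons, and the end-to-end pipeline.

Pairwise results are collected into region+layer matrices of ``mean ± SEM
(n)`` cells mirroring the usual publication layout (SEM across slices; the
pooled number of coincident bursts is reported separately). Group-level
comparisons use the Wilcoxon signed-rank test, exact for small samples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import bursts as burst_mod
from . import anatomy as anatomy_mod
from . import synthetic
from .spiketrain import SpikeTrain, write_spike_trains


@dataclass
class PairMatrix:
    """Matrix of mean ± SEM (pooled n) entries over region+layer labels."""

    labels: tuple[str, ...]
    metric: str
    means: np.ndarray
    sems: np.ndarray
    ns: np.ndarray          # pooled event counts
    n_slices: np.ndarray    # number of per-slice values behind each cell

    def cell(self, i: int, j: int) -> str:
        if not np.isfinite(self.means[i, j]):
            return ""
        return f"{self.means[i, j]:.2f} ± {self.sems[i, j]:.2f} (n = {int(self.ns[i, j])})"

    def to_frame(self) -> pd.DataFrame:
        data = [[self.cell(i, j) for j in range(len(self.labels))] for i in range(len(self.labels))]
        return pd.DataFrame(data, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def aggregate_matrix(
    records: Sequence[Mapping],
    metric: str,
    labels: Sequence[str] | None = None,
) -> PairMatrix:
    """Aggregate per-slice pair records into a matrix.

    Each record needs keys ``row``, ``col``, ``value`` and ``n`` (the pair's
    coincident-burst count). Cells with no records stay missing (NaN), never
    zero. SEM uses the across-slice sample SD; a single value gets SEM 0 by
    convention.
    """
    if labels is None:
        seen = []
        for r in records:
            for key in (r["row"], r["col"]):
                if key not in seen:
                    seen.append(key)
        labels = tuple(seen)
    else:
        labels = tuple(labels)
    k = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    values: dict[tuple[int, int], list[float]] = {}
    ns = np.zeros((k, k), dtype=int)
    for r in records:
        i, j = idx[r["row"]], idx[r["col"]]
        v = r["value"]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        values.setdefault((i, j), []).append(float(v))
        ns[i, j] += int(r.get("n", 0))
    means = np.full((k, k), np.nan)
    sems = np.full((k, k), np.nan)
    n_slices = np.zeros((k, k), dtype=int)
    for (i, j), vals in values.items():
        arr = np.asarray(vals)
        means[i, j] = arr.mean()
        sems[i, j] = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        n_slices[i, j] = arr.size
    return PairMatrix(labels=labels, metric=metric, means=means, sems=sems, ns=ns,
                      n_slices=n_slices)


def records_from_pairs(
    results: Sequence[burst_mod.PairCoincidence],
    label_of: Mapping[str, str],
    metric: str = "coincidence_ratio",
) -> list[dict]:
    """Flatten PairCoincidence results into matrix records.

    For ``coincidence_ratio`` the matrix is symmetric with a unit diagonal
    (every burst coincides with itself); for ``lead_ratio`` entry (i, j) is
    the fraction of coinciding pairs in which channel i's burst led.
    """
    recs = []
    for r in results:
        la, lb = label_of[r.channel_a], label_of[r.channel_b]
        if metric == "coincidence_ratio":
            recs.append({"row": la, "col": lb, "value": r.coincidence_ratio, "n": r.n_coincident})
            recs.append({"row": lb, "col": la, "value": r.coincidence_ratio, "n": r.n_coincident})
        elif metric == "lead_ratio":
            recs.append({"row": la, "col": lb, "value": r.lead_ratio_a, "n": r.n_coincident})
            recs.append({"row": lb, "col": la, "value": r.lead_ratio_b, "n": r.n_coincident})
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return recs


@dataclass
class GroupComparison:
    """Wilcoxon signed-rank comparison of paired samples."""

    name: str
    statistic: float
    p_value: float
    n: int

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def wilcoxon_paired(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    name: str = "",
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    Exact null distribution for n <= 25 non-zero differences, normal
    approximation with continuity correction above; all-zero differences
    give p = 1.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = int(np.sum(d != 0))
    if nz == 0:
        return GroupComparison(name=name, statistic=0.0, p_value=1.0, n=0)
    method = "exact" if nz <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True, method=method)
    return GroupComparison(name=name, statistic=float(res.statistic), p_value=float(res.pvalue), n=nz)


def directionality_report(
    lead_ratios: Mapping[str, Sequence[float]],
    surrogate_lead_ratios: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Per-connection test of lead ratios against the chance level 0.5.

    One row per connection: the observed distribution of per-pair lead
    ratios, the surrogate distribution (if given), a Wilcoxon signed-rank
    test against 0.5 and significance stars. Connections with fewer than two
    pairs are reported descriptively (no test).
    """
    rows = []
    for name, vals in lead_ratios.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        row = {
            "connection": name,
            "n_pairs": arr.size,
            "mean_lead_ratio": float(arr.mean()) if arr.size else float("nan"),
        }
        if arr.size >= 2:
            cmp = wilcoxon_paired(arr, np.full(arr.size, 0.5), name=name)
            row["p_value"] = cmp.p_value
            row["stars"] = cmp.stars
        else:
            row["p_value"] = float("nan")
            row["stars"] = ""
        if surrogate_lead_ratios and name in surrogate_lead_ratios:
            surr = np.asarray(list(surrogate_lead_ratios[name]), dtype=float)
            surr = surr[np.isfinite(surr)]
            row["surrogate_mean"] = float(surr.mean()) if surr.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved in the outdir."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "ephys": {
        "span_s": 1200.0,
        "channels": [
            {"id": "s1_sp", "region": "S1Bf", "layer": "SP", "burst_rate": 2.0},
            {"id": "s1_l56", "region": "S1Bf", "layer": "L5/6", "burst_rate": 1.2},
            {"id": "m1_sp", "region": "M1", "layer": "SP", "burst_rate": 1.9},
            {"id": "m1_l56", "region": "M1", "layer": "L5/6", "burst_rate": 1.1},
        ],
        "couplings": [
            {"source": "s1_sp", "target": "s1_l56", "prob": 0.5, "lag_ms": 150.0},
            {"source": "s1_sp", "target": "m1_sp", "prob": 0.4, "lag_ms": 150.0},
            {"source": "m1_sp", "target": "m1_l56", "prob": 0.5, "lag_ms": 150.0},
        ],
    },
    "bursts": {"isi_max_ms": 300.0, "min_spikes": 3},
    "coincidence": {"jitter_ms": 750.0, "n_surrogates": 200, "percentile": 99.0},
    "anatomy": {
        "area": "S1Bf",
        "n_neurons": 2000,
        "backlabel_probs": {"MZ": 0.0, "CP": 0.01, "L5": 0.05, "L6": 0.04, "SP": 0.03},
        "exclude": ["MZ"],
        "alpha": 0.05,
    },
}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int | None = None) -> dict:
    """simulate -> detect bursts -> coincidence -> anatomy -> report.

    ``config`` is a dict or a YAML path; ``seed`` overrides the config seed.
    Every stage writes its outputs under ``outdir``; a manifest records
    parameters, seeds, and output hashes so a rerun with the same config and
    seed is byte-identical.
    """
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise PipelineError(f"config file not found: {cfg_path}")
        config = yaml.safe_load(cfg_path.read_text())
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_children = np.random.SeedSequence(cfg["seed"]).spawn(4)
    bundle: dict = {"config": cfg}

    stage = "simulate-ephys"
    try:
        e = cfg["ephys"]
        models = {
            ch["id"]: synthetic.BurstModel(
                burst_rate=ch.get("burst_rate", 1.5),
                isolated_spike_rate=ch.get("isolated_spike_rate", 0.1),
                recording_span=e["span_s"],
            )
            for ch in e["channels"]
        }
        labels = {ch["id"]: (ch["region"], ch["layer"]) for ch in e["channels"]}
        couplings = [
            synthetic.CouplingSpec(
                source_channel=c["source"],
                target_channel=c["target"],
                coupling_prob=c["prob"],
                lag_dist=("norm", {"loc": c["lag_ms"] / 1000.0, "scale": c.get("lag_sd_ms", 20.0) / 1000.0}),
            )
            for c in e["couplings"]
        ]
        trains = synthetic.generate_coupled_ensemble(
            models, couplings, seed=rng_children[0], labels=labels
        )
        write_spike_trains(trains, out / "spikes.csv")

        stage = "bursts"
        bcfg = cfg["bursts"]
        isi_max = bcfg["isi_max_ms"] / 1000.0
        stats_rows = []
        bursts_by_channel = {}
        for tr in trains:
            bs = burst_mod.detect_bursts(tr, isi_max, bcfg["min_spikes"])
            bursts_by_channel[tr.channel_id] = bs
            st = burst_mod.burst_stats(bs, tr.span)
            stats_rows.append(
                {
                    "channel": tr.channel_id,
                    "region": tr.region,
                    "layer": tr.layer,
                    "n_bursts": st.n_bursts,
                    "occurrence_per_min": st.occurrence_per_min,
                    "mean_duration_ms": st.mean_duration_s * 1000.0,
                    "mean_n_spikes": st.mean_n_spikes,
                    "mean_intra_freq_hz": st.mean_intra_freq_hz,
                }
            )
        burst_table = pd.DataFrame(stats_rows)
        burst_table.to_csv(out / "burst_stats.tsv", sep="\t", index=False)
        bundle["burst_stats"] = stats_rows

        stage = "coincidence"
        ccfg = cfg["coincidence"]
        pair_results = []
        pair_rngs = synthetic.substreams(
            int(rng_children[1].generate_state(1)[0] % (2**31)),
            len(trains) * (len(trains) - 1) // 2,
        )
        k = 0
        for i in range(len(trains)):
            for j in range(i + 1, len(trains)):
                res = burst_mod.coincidence_significance(
                    trains[i],
                    trains[j],
                    n_surrogates=ccfg["n_surrogates"],
                    half_width=ccfg["jitter_ms"] / 1000.0,
                    percentile=ccfg["percentile"],
                    isi_max=isi_max,
                    min_spikes=bcfg["min_spikes"],
                    seed=pair_rngs[k],
                )
                pair_results.append(res)
                k += 1
        label_of = {tr.channel_id: f"{tr.region} {tr.layer}" for tr in trains}
        pair_json = [
            {
                "channel_a": r.channel_a,
                "channel_b": r.channel_b,
                "n_bursts_a": r.n_bursts_a,
                "n_bursts_b": r.n_bursts_b,
                "n_coincident": r.n_coincident,
                "coincidence_ratio": r.coincidence_ratio,
                "lead_ratio_a": r.lead_ratio_a,
                "lead_ratio_b": r.lead_ratio_b,
                "tie_ratio": r.tie_ratio,
                "surrogate_p99": r.threshold,
                "significant": r.significant,
            }
            for r in pair_results
        ]
        (out / "pair_coincidence.json").write_text(json.dumps(pair_json, indent=2, default=float))
        diag = [
            {"row": label_of[t.channel_id], "col": label_of[t.channel_id], "value": 1.0,
             "n": len(bursts_by_channel[t.channel_id])}
            for t in trains
        ]
        coin = aggregate_matrix(
            records_from_pairs(pair_results, label_of, "coincidence_ratio") + diag,
            "coincidence_ratio",
        )
        lead = aggregate_matrix(
            records_from_pairs(pair_results, label_of, "lead_ratio"), "lead_ratio"
        )
        coin.to_tsv(out / "coincidence_matrix.tsv")
        lead.to_tsv(out / "lead_matrix.tsv")
        bundle["pairs"] = pair_json

        stage = "anatomy"
        acfg = cfg["anatomy"]
        scheme = anatomy_mod.load_scheme(acfg["area"])
        vol = synthetic.VolumeSpec(area=acfg["area"], n_neurons=acfg["n_neurons"])
        cloud, pial_pts, sp_pts = synthetic.generate_cortical_volume(
            vol, scheme, seed=rng_children[2]
        )
        cloud = synthetic.sample_backlabeled(cloud, acfg["backlabel_probs"], seed=rng_children[3])
        synthetic.write_cell_cloud(cloud, out / "cells.csv")
        synthetic.write_surfaces(pial_pts, sp_pts, out / "surfaces.csv")
        pial = anatomy_mod.fit_surface(pial_pts)
        sp = anatomy_mod.fit_surface(sp_pts)
        cells = anatomy_mod.normalized_depths(cloud, pial, sp, scheme)
        cells.to_csv(out / "cells_with_depth.csv", index=False, float_format="%.5f")
        counts = anatomy_mod.count_layers(cells)
        enrich = anatomy_mod.enrichment_test(
            counts.to_dict(), scheme, exclude=tuple(acfg["exclude"]), alpha=acfg["alpha"]
        )
        bundle["anatomy"] = {
            "chi2": enrich.chi2,
            "df": enrich.df,
            "p_value": enrich.p_value,
            "binomial_p": enrich.binomial_p,
            "direction": enrich.direction,
            "observed": {l: int(v) for l, v in zip(enrich.layers, enrich.observed)},
        }
        (out / "enrichment.json").write_text(json.dumps(bundle["anatomy"], indent=2, default=float))

        stage = "report"
        outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
        manifest = {
            "seed": cfg["seed"],
            "config": cfg,
            "outputs": {p.name: _hash_file(p) for p in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = manifest
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - annotate stage, keep partial outputs
        raise PipelineError(f"pipeline stage '{stage}' failed: {err}") from err
    return bundle
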