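"""End-to-end orchestration: synth -> preprocess -> scores -> connectivity -> stats.

A :class:`RunConfig` fully determines a run: the synthetic-study
configuration, which analysis branches to execute, the permutation count
and the seeds. Outputs are plain CSV/JSON files plus a human-readable
summary and a manifest (config hash, versions, seeds), and a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import (
    BANDS,
    autospectrum_index,
    band_analytic,
    hilbert_amplitude_index,
    icoh_matrix,
    plv_matrix,
)
from .layout import channel_layout, scalp_channels
from .preprocess import preprocess_cortical, preprocess_ffr
from .spectral import assr_scores, ffr_scores
from .stats import (
    channel_adjacency,
    cluster_permutation,
    edge_adjacency,
    edge_pairs,
    holm,
    neurophenomenological_contrast,
    perm_paired_t,
    perm_rm_anova,
)
from .synth import (
    BEATS_HZ,
    CONDITIONS,
    EXPERIMENTAL_CONDITIONS,
    SynthConfig,
    config_to_dict,
    generate_study,
)

logger = logging.getLogger(__name__)

#: factorial column order (A1B1, A1B2, A2B1, A2B2): A = beat type, B = frequency
FACTORIAL_ORDER = (
    "binaural_theta",
    "binaural_gamma",
    "monaural_theta",
    "monaural_gamma",
)

#: paired condition contrasts entering the cluster tests
CONTRASTS = (
    ("binaural_theta", "baseline"),
    ("binaural_gamma", "baseline"),
    ("monaural_theta", "baseline"),
    ("monaural_gamma", "baseline"),
    ("binaural_theta", "monaural_theta"),
    ("binaural_gamma", "monaural_gamma"),
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    out_dir: str = "beatpipe_out"
    n_perm: int = 1000
    seed: int = 0
    run_ffr: bool = True
    run_assr: bool = True
    run_connectivity: bool = True
    run_neurophen: bool = True
    bands: tuple[str, ...] = tuple(BANDS)
    fs_cortical: float = 512.0
    window_s: float = 8.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = config_to_dict(self.synth)
        d["bands"] = list(self.bands)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        if isinstance(synth, dict):
            synth.setdefault("coupled_pairs", [])
            synth["coupled_pairs"] = [
                (p[0], p[1], tuple(p[2]), p[3], p[4]) for p in synth["coupled_pairs"]
            ]
            synth = SynthConfig(**synth)
        if "bands" in d:
            d["bands"] = tuple(d["bands"])
        return cls(synth=synth, **d)


def demo_config(out_dir: str = "beatpipe_out", seed: int = 0) -> RunConfig:
    """Desk-scale profile: 8 subjects, 16 channels, 64-s blocks, 200 permutations.

    fs stays at 1024 Hz so the ~400-Hz carriers remain representable for
    the FFR branch; the cortical branch still resamples to 512 Hz.
    """
    return RunConfig(
        synth=SynthConfig(
            n_subjects=8, fs=1024.0, n_channels=16, block_s=64.0, seed=seed
        ),
        out_dir=out_dir,
        n_perm=200,
        seed=seed,
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _perm_summary(res) -> dict:
    return {
        "F": res.observed_stat,
        "p": res.p,
        "null_ci": list(res.ci),
        "n_perm": res.n_perm,
        "seed": res.seed,
    }


def _cluster_summary(clusters, band_names, unit_labels) -> list[dict]:
    return [
        {
            "band": band_names[c.band],
            "polarity": c.polarity,
            "mass": c.mass,
            "p": c.p,
            "n_points": c.size,
            "members": [unit_labels[u] for _, u in c.members],
        }
        for c in clusters
    ]


def _scores_matrix(table: pd.DataFrame, target) -> np.ndarray:
    """subjects x FACTORIAL_ORDER matrix of dB scores for one target."""
    sub = table[table["target"] == target]
    pivot = sub.pivot(index="subject", columns="condition", values="db_change")
    return pivot[list(FACTORIAL_ORDER)].to_numpy()


def _factorial_block(table: pd.DataFrame, target, n_perm: int, seed: int) -> dict:
    scores = _scores_matrix(table, target)
    res = perm_rm_anova(
        scores, design="factorial_2x2", n_perm=n_perm, seed=seed,
        factor_names=("beat_type", "frequency"),
    )
    block = {name: _perm_summary(r) for name, r in res.items()}
    if res["interaction"].p <= 0.05:
        pairs = [
            ("monaural_gamma", "binaural_gamma"),
            ("monaural_gamma", "monaural_theta"),
            ("binaural_gamma", "binaural_theta"),
        ]
        raw, details = [], []
        cond_idx = {c: i for i, c in enumerate(FACTORIAL_ORDER)}
        for k, (a, b) in enumerate(pairs):
            t_res = perm_paired_t(
                scores[:, cond_idx[a]], scores[:, cond_idx[b]],
                n_perm=n_perm, seed=seed + 17 * (k + 1),
            )
            raw.append(t_res.p)
            details.append({"pair": [a, b], "t": t_res.observed_stat, "p": t_res.p})
        reject, p_adj = holm(raw)
        for d, r, pa in zip(details, reject, p_adj):
            d["p_holm"] = float(pa)
            d["reject"] = bool(r)
        block["post_hoc"] = details
    return block


def connectivity_maps(
    recordings: dict,
    cfg: RunConfig,
) -> tuple[dict, dict, list[str], list[tuple[int, int]]]:
    """Per-condition local and pairwise synchronization maps.

    Returns ``(local, pairwise, scalp_names, pairs)`` where
    ``local[metric][condition]`` is subjects x bands x scalp-channels and
    ``pairwise[metric][condition]`` is subjects x bands x pairs, for
    metrics ``hilbert``/``power`` and ``plv``/``icoh`` respectively.
    """
    names, _ = channel_layout(cfg.synth.n_channels)
    scalp = scalp_channels(names)
    scalp_names = [names[i] for i in scalp]
    pairs = edge_pairs(len(scalp))
    n_subj = cfg.synth.n_subjects
    n_bands = len(cfg.bands)
    local = {
        m: {c: np.zeros((n_subj, n_bands, len(scalp))) for c in CONDITIONS}
        for m in ("hilbert", "power")
    }
    pairwise = {
        m: {c: np.zeros((n_subj, n_bands, len(pairs))) for c in CONDITIONS}
        for m in ("plv", "icoh")
    }
    pair_rows = np.array([p[0] for p in pairs])
    pair_cols = np.array([p[1] for p in pairs])
    for (s, condition), rec in recordings.items():
        continuous, fs, _ = preprocess_cortical(
            rec, fs_target=cfg.fs_cortical, return_continuous=True
        )
        data = continuous[scalp]
        for b, band_name in enumerate(cfg.bands):
            band = BANDS[band_name]
            analytic = band_analytic(data, fs, band)
            local["hilbert"][condition][s, b] = hilbert_amplitude_index(
                analytic, cfg.window_s
            )
            pm = plv_matrix(analytic.phase, fs, cfg.window_s)
            pairwise["plv"][condition][s, b] = pm[pair_rows, pair_cols]
            im = icoh_matrix(data, fs, band, cfg.window_s)
            pairwise["icoh"][condition][s, b] = im[pair_rows, pair_cols]
            local["power"][condition][s, b] = autospectrum_index(
                data, fs, band, cfg.window_s
            )
    return local, pairwise, scalp_names, pairs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages; write outputs under ``cfg.out_dir``.

    Returns the summary dictionary that is also written to
    ``results.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"conditions": list(CONDITIONS)}

    def stage(name):
        logger.info("stage %-14s t=%.1fs", name, time.time() - t0)

    stage("synth")
    try:
        recordings, vas = generate_study(cfg.synth, seed=cfg.seed)
    except Exception as exc:  # pragma: no cover - abort path
        raise RuntimeError(f"stage synth failed: {exc}") from exc
    vas.to_csv(out / "vas.csv", index=False)

    # VAS one-way permutation RM-ANOVA, 5-level condition factor
    vas_block = {}
    for scale in ("mental_relaxation", "absorption_depth"):
        pivot = vas.pivot(index="subject", columns="condition", values=scale)
        res = perm_rm_anova(
            pivot[list(CONDITIONS)].to_numpy(), design="one_way",
            n_perm=cfg.n_perm, seed=cfg.seed + 101,
        )
        vas_block[scale] = _perm_summary(res)
    summary["vas"] = vas_block

    if cfg.run_ffr:
        stage("ffr")
        ffr_epochs = {k: preprocess_ffr(rec) for k, rec in recordings.items()}
        ffr_table = ffr_scores(ffr_epochs)
        ffr_table.to_csv(out / "ffr_scores.csv", index=False)
        summary["ffr"] = {
            family: _factorial_block(ffr_table, family, cfg.n_perm, cfg.seed + 211)
            for family in ("theta", "gamma")
        }
        del ffr_epochs

    cortical_epochs = None
    if cfg.run_assr:
        stage("assr")
        cortical_epochs = {
            k: preprocess_cortical(rec, fs_target=cfg.fs_cortical)
            for k, rec in recordings.items()
        }
        assr_table = assr_scores(cortical_epochs)
        assr_table.to_csv(out / "assr_scores.csv", index=False)
        summary["assr"] = {
            f"{beat_hz:g}Hz": _factorial_block(
                assr_table, beat_hz, cfg.n_perm, cfg.seed + 307
            )
            for beat_hz in (BEATS_HZ["theta"], BEATS_HZ["gamma"])
        }
        del cortical_epochs

    if cfg.run_connectivity or cfg.run_neurophen:
        stage("connectivity")
        local, pairwise, scalp_names, pairs = connectivity_maps(recordings, cfg)
        names, positions = channel_layout(cfg.synth.n_channels)
        scalp = scalp_channels(names)
        chan_adj = channel_adjacency(positions[scalp])
        pair_adj = edge_adjacency(pairs)
        pair_labels = [f"{scalp_names[i]}-{scalp_names[j]}" for i, j in pairs]
        band_names = list(cfg.bands)

        if cfg.run_connectivity:
            stage("cluster_stats")
            cluster_block: dict = {}
            for metric, maps, adj, labels in (
                ("hilbert", local["hilbert"], chan_adj, scalp_names),
                ("power", local["power"], chan_adj, scalp_names),
                ("plv", pairwise["plv"], pair_adj, pair_labels),
                ("icoh", pairwise["icoh"], pair_adj, pair_labels),
            ):
                per_contrast = {}
                for a, b in CONTRASTS:
                    clusters = cluster_permutation(
                        maps[a], maps[b], adj, n_perm=cfg.n_perm,
                        seed=cfg.seed + 401,
                    )
                    per_contrast[f"{a}_vs_{b}"] = _cluster_summary(
                        clusters, band_names, labels
                    )
                cluster_block[metric] = per_contrast
            summary["clusters"] = cluster_block
            _dump(out / "clusters.json", cluster_block)

        if cfg.run_neurophen:
            stage("neurophen")
            neuro_block: dict = {}
            for scale in ("mental_relaxation", "absorption_depth"):
                per_metric = {}
                for metric, maps, adj, labels in (
                    ("hilbert", local["hilbert"], chan_adj, scalp_names),
                    ("power", local["power"], chan_adj, scalp_names),
                    ("plv", pairwise["plv"], pair_adj, pair_labels),
                    ("icoh", pairwise["icoh"], pair_adj, pair_labels),
                ):
                    exp_maps = {c: maps[c] for c in EXPERIMENTAL_CONDITIONS}
                    _, clusters = neurophenomenological_contrast(
                        exp_maps, vas, scale, adj, n_perm=cfg.n_perm,
                        seed=cfg.seed + 503,
                    )
                    per_metric[metric] = _cluster_summary(
                        clusters, band_names, labels
                    )
                neuro_block[scale] = per_metric
            summary["neurophen"] = neuro_block
            _dump(out / "neurophen.json", neuro_block)

    stage("report")
    summary["elapsed_s"] = round(time.time() - t0, 2)
    hashed = {k: v for k, v in cfg.to_dict().items() if k != "out_dir"}
    config_json = json.dumps(hashed, sort_keys=True, default=_json_default)
    summary["manifest"] = {
        "beatpipe_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
    }
    results = {k: v for k, v in summary.items() if k not in ("elapsed_s", "manifest")}
    _dump(out / "results.json", results)
    _dump(out / "manifest.json", summary["manifest"])
    (out / "summary.txt").write_text(render_summary(results))
    return summary


def render_summary(results: dict) -> str:
    """Human-readable per-condition tables and cluster listings."""
    lines = ["beatpipe run summary", "====================", ""]
    if "vas" in results:
        lines.append("VAS one-way permutation RM-ANOVA (5 conditions):")
        for scale, res in results["vas"].items():
            lines.append(
                f"  {scale:18s} F = {res['F']:.3f}  p = {res['p']:.3f}"
                f"  null CI = [{res['null_ci'][0]:.2f}, {res['null_ci'][1]:.2f}]"
            )
        lines.append("")
    for key, title in (("ffr", "FFR dB scores"), ("assr", "ASSR dB scores")):
        if key in results:
            lines.append(f"{title} — factorial (2x2) permutation RM-ANOVA:")
            for target, block in results[key].items():
                lines.append(f"  target {target}:")
                for effect in ("beat_type", "frequency", "interaction"):
                    res = block[effect]
                    lines.append(
                        f"    {effect:12s} F = {res['F']:.3f}  p = {res['p']:.3f}"
                    )
                for ph in block.get("post_hoc", []):
                    lines.append(
                        f"    post hoc {ph['pair'][0]} vs {ph['pair'][1]}: "
                        f"t = {ph['t']:.2f}  p_holm = {ph['p_holm']:.3f}"
                        f"{'  *' if ph['reject'] else ''}"
                    )
            lines.append("")
    for key, title in (
        ("clusters", "Condition-contrast clusters"),
        ("neurophen", "Neurophenomenological clusters"),
    ):
        if key in results:
            lines.append(f"{title}:")
            count = 0
            for group, sub in results[key].items():
                for name, clusters in sub.items():
                    for c in clusters:
                        count += 1
                        lines.append(
                            f"  {group}/{name}: {c['polarity']} cluster at "
                            f"{c['band']}, mass = {c['mass']:.2f}, "
                            f"p = {c['p']:.3f}, {c['n_points']} points"
                        )
            if count == 0:
                lines.append("  none significant")
            lines.append("")
    return "\n".join(lines)
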