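"""End-to-end study analysis: from per-subject recordings (or generated maps)
to cluster statistics, FDR-corrected brain-behaviour correlations, and a
serialized results bundle.

The analysis replicates the within-subject design: per subject and condition,
stage-restricted band power (SWA in N2/N3, theta in REM, 12-16 Hz in N2/N3)
and spindle-event metrics per electrode; intra-individual trauma-minus-neutral
change scores; paired cluster tests per measure; one-sided cluster Spearman
correlations of sleep changes against heart-rate reactivity and behavioural
outcomes, with Storey FDR over the four correlations per outcome and
percentile-bootstrap CIs for significant clusters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import spectra, spindles
from .clusterstats import (build_graph, cluster_mean_corr, cluster_paired_t,
                           cluster_spearman, storey_fdr)
from .power import required_n_correlation  # noqa: F401  (pipeline surface)
from .preprocess import highpass, rereference, segment
from .synth import HR_WINDOW, SLEEP_MEASURES, Cohort

log = logging.getLogger("psgstats")

#: hypothesised direction of each correlation family (one-sided tails)
CORRELATION_TAILS = {
    "intrusions": "left",   # more oscillatory activity -> fewer intrusions
    "affect": "left",       # -> less negative affect
    "hr": "right",          # higher film reactivity -> stronger sleep response
}


@dataclass
class StudyConfig:
    """Every analysis choice that shows up in an output lives here."""

    bands: dict = field(default_factory=lambda: dict(spectra.BANDS))
    band_stages: dict = field(default_factory=lambda: {
        "swa": ["N2", "N3"], "rem_theta": ["REM"], "spindle": ["N2", "N3"]})
    epoch_len_s: float = 8.192
    overlap: float = 0.5
    mastoid_refs: tuple = ("M1", "M2")
    highpass_hz: float = 0.1
    spindle_thresh_sd: float = 1.5
    graph_method: str = "distance"
    graph_threshold: float | None = None
    alpha_sample: float = 0.05
    alpha_cluster: float = 0.05
    n_perm: int = 1000
    paired_tail: str = "two"
    correlation_tails: dict = field(
        default_factory=lambda: dict(CORRELATION_TAILS))
    fdr_lambda: float = 0.5
    n_boot: int = 1000
    hr_window: tuple = HR_WINDOW
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "mastoid_refs" in raw:
            raw["mastoid_refs"] = tuple(raw["mastoid_refs"])
        if "hr_window" in raw:
            raw["hr_window"] = tuple(raw["hr_window"])
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        return cls(**raw)


def _plain(x):
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if isinstance(x, np.generic):
        return x.item()
    return x


@dataclass
class StudyResults:
    """Results bundle: maps, cluster tests, correlations, q-values, CIs."""

    config: StudyConfig
    subjects: list[str]
    channels: list[str]
    change_maps: dict                    # measure -> (n_subj, n_ch)
    outcomes: dict                       # outcome -> (n_subj,)
    paired: dict                         # measure -> ClusterResults
    correlations: dict                   # (outcome, measure) -> ClusterResults
    qvalues: dict                        # outcome -> {measure: q}
    cluster_rho: dict                    # (outcome, measure) -> (rho, ci)
    sam_tests: dict = field(default_factory=dict)  # (cond, scale) -> (t, p)
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Study analysis: {len(self.subjects)} subjects, "
                 f"{len(self.channels)} channels"]
        if self.sam_tests:
            lines += ["", "Film manipulation check (SAM pre vs post, "
                          "paired t):"]
            for (cond, scale), (t, p) in self.sam_tests.items():
                lines.append(f"  {cond:8s} {scale:8s} t = {t:+.2f}  "
                             f"p = {p:.4f}")
        lines += ["", "Paired condition contrasts (two-tailed):"]
        for m, res in self.paired.items():
            lines.append(f"  {m:18s} min cluster p = {res.min_p:.4f} "
                         f"({len(res.clusters)} clusters)")
        for outcome in self.qvalues:
            tail = self.config.correlation_tails[outcome]
            lines.append("")
            lines.append(f"Sleep-change vs {outcome} "
                         f"(one-sided {tail}, Storey FDR over "
                         f"{len(self.qvalues[outcome])} tests):")
            for m, q in self.qvalues[outcome].items():
                res = self.correlations[(outcome, m)]
                extra = ""
                if (outcome, m) in self.cluster_rho:
                    rho, ci = self.cluster_rho[(outcome, m)]
                    extra = (f"  cluster rho = {rho:+.3f}"
                             + (f", 95% CI [{ci[0]:+.3f}, {ci[1]:+.3f}]"
                                if ci else ""))
                lines.append(f"  {m:18s} p = {res.min_p:.4f}  q = {q:.4f}"
                             f"{extra}")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        for m, arr in self.change_maps.items():
            pd.DataFrame(arr, index=self.subjects, columns=self.channels
                         ).to_csv(out / f"change_{m}.tsv", sep="\t")
        pd.DataFrame(self.outcomes, index=self.subjects).to_csv(
            out / "outcomes.tsv", sep="\t")
        bundle = {
            "paired": {m: r.to_dict() for m, r in self.paired.items()},
            "correlations": {f"{o}:{m}": r.to_dict()
                             for (o, m), r in self.correlations.items()},
            "qvalues": self.qvalues,
            "cluster_rho": {
                f"{o}:{m}": {"rho": rho, "ci": list(ci) if ci else None}
                for (o, m), (rho, ci) in self.cluster_rho.items()},
        }
        with open(out / "clusters.json", "w") as fh:
            json.dump(_plain(bundle), fh, indent=1)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        with open(out / "run.log", "w") as fh:
            fh.write("resolved analysis parameters\n")
            for k, v in sorted(_plain(asdict(self.config)).items()):
                fh.write(f"  {k} = {v}\n")
            for k, v in sorted(self.provenance.items()):
                fh.write(f"  {k} = {v}\n")


# ---------------------------------------------------------------------------
# measurement: recordings -> per-channel maps
# ---------------------------------------------------------------------------

def measure_subject(rec, hyp, cfg: StudyConfig, montage):
    """One subject-condition measurement pass over a recording.

    Re-references to the mastoid pair, high-pass filters, and derives every
    per-channel sleep measure the study analyses.
    """
    rec = rereference(rec, cfg.mastoid_refs)
    rec = highpass(rec, cfg.highpass_hz)
    eeg_labels = [l for l, t in zip(rec.labels, rec.types) if t == "EEG"]
    eeg_idx = [rec.index(l) for l in eeg_labels]
    out = {}
    for name, band in cfg.bands.items():
        key = "rem_theta" if name == "theta" else name
        stage_set = set(cfg.band_stages[key if key in cfg.band_stages
                                        else name])
        eps = segment(rec, hyp, stage_set, cfg.epoch_len_s, cfg.overlap)
        bp = spectra.band_power(spectra.spectrum(eps), band)
        out[key] = np.asarray(bp)[eeg_idx]
    events = spindles.detect_spindles(rec, hyp,
                                      thresh_sd=cfg.spindle_thresh_sd,
                                      channels=eeg_labels)
    per_ch = spindles.metrics_by_channel(events, hyp, eeg_labels)
    out["spindle_count"] = np.array([per_ch[l].count for l in eeg_labels],
                                    dtype=float)
    out["spindle_density"] = np.array([per_ch[l].density for l in eeg_labels])
    out["spindle_envelope"] = np.array([per_ch[l].envelope
                                        for l in eeg_labels])
    out["_labels"] = eeg_labels
    return out


def cohort_maps(cohort: Cohort, cfg: StudyConfig) -> dict:
    """Subject x channel maps per measure and condition.

    For an ``"eeg"`` cohort the maps are measured from the waveforms through
    the full preprocessing and spectral chain; for a ``"maps"`` cohort the
    generated maps are used directly.
    """
    if cohort.config.signal_mode == "maps":
        return cohort.maps
    maps = {m: {c: [] for c in ("trauma", "neutral")} for m in SLEEP_MEASURES}
    for s in cohort.subjects:
        hyp = cohort.hypnograms[s]
        for cond in ("trauma", "neutral"):
            meas = measure_subject(cohort.recordings[(s, cond)], hyp, cfg,
                                   cohort.montage)
            for m in SLEEP_MEASURES:
                key = m if m in meas else {"swa": "swa"}.get(m, m)
                maps[m][cond].append(meas[key])
    return {m: {c: np.vstack(v) for c, v in d.items()}
            for m, d in maps.items()}


# ---------------------------------------------------------------------------
# study composition
# ---------------------------------------------------------------------------

def run_study(cohort: Cohort, config: StudyConfig | None = None,
              out_dir=None) -> StudyResults:
    """Run the full analysis on a cohort and optionally save the bundle."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    maps = cohort_maps(cohort, cfg)
    graph = build_graph(cohort.montage, cfg.graph_method, cfg.graph_threshold,
                        labels=cohort.eeg_labels)
    change = {m: maps[m]["trauma"] - maps[m]["neutral"]
              for m in SLEEP_MEASURES}
    outcomes = {o: cohort.outcome_vector(o)
                for o in ("intrusions", "affect", "hr")}

    paired = {}
    for m in SLEEP_MEASURES:
        paired[m] = cluster_paired_t(
            maps[m]["trauma"], maps[m]["neutral"], graph,
            alpha_sample=cfg.alpha_sample, alpha_cluster=cfg.alpha_cluster,
            n_perm=cfg.n_perm, tail=cfg.paired_tail,
            seed=int(rng.integers(2**31)))
        log.info("paired %s: min p %.4f", m, paired[m].min_p)

    correlations = {}
    qvalues = {}
    cluster_rho = {}
    for outcome in ("hr", "intrusions", "affect"):
        tail = cfg.correlation_tails[outcome]
        y = outcomes[outcome]
        ps = {}
        for m in SLEEP_MEASURES:
            res = cluster_spearman(
                change[m], y, graph, alpha_sample=cfg.alpha_sample,
                alpha_cluster=cfg.alpha_cluster, n_perm=cfg.n_perm,
                tail=tail, seed=int(rng.integers(2**31)))
            correlations[(outcome, m)] = res
            ps[m] = res.min_p
        qs = storey_fdr(np.array(list(ps.values())), cfg.fdr_lambda)
        qvalues[outcome] = dict(zip(ps.keys(), (float(q) for q in qs)))
        for m in SLEEP_MEASURES:
            res = correlations[(outcome, m)]
            for c in res.significant_clusters():
                rho, ci = cluster_mean_corr(
                    change[m], c.indices, y, n_boot=cfg.n_boot,
                    seed=int(rng.integers(2**31)))
                cluster_rho[(outcome, m)] = (rho, ci)
                break   # report the strongest (first) significant cluster
    sam_tests = {}
    if getattr(cohort, "sam", None) is not None:
        from .behavior import paired_prepost_t
        for cond in ("trauma", "neutral"):
            sub = cohort.sam[cohort.sam["condition"] == cond]
            for scale in ("mood", "arousal"):
                pre = sub.loc[sub["time"] == "pre", scale].to_numpy(float)
                post = sub.loc[sub["time"] == "post", scale].to_numpy(float)
                sam_tests[(cond, scale)] = paired_prepost_t(pre, post)

    import hashlib
    prov = {
        "seed": cfg.seed,
        "cohort_seed": cohort.truth.seed,
        "signal_mode": cohort.config.signal_mode,
        "diary_md5": hashlib.md5(
            cohort.diary.to_csv(index=False).encode()).hexdigest(),
        "affect_md5": hashlib.md5(
            cohort.affect.to_csv(index=False).encode()).hexdigest(),
    }
    results = StudyResults(cfg, list(cohort.subjects),
                           list(cohort.eeg_labels), change, outcomes,
                           paired, correlations, qvalues, cluster_rho,
                           sam_tests, prov)
    if out_dir is not None:
        results.save(out_dir)
    return results
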