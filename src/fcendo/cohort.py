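"""Synthetic three-group cohort generator (controls / unaffected siblings /
patients) with planted, recoverable effects.

Each subject gets a generative Watts–Strogatz graph whose rewiring
probability differs by group — patient networks are more random (low
clustering, high efficiency), control networks more lattice-like, siblings
intermediate — and a sibling's rewiring parameter is correlated with its
paired patient's.  BOLD-like time series are built from four ingredients:

1. latent network component time courses mixed through spatially localised
   component maps, with a planted directed coupling from a designated
   "source" network into a "target" network that is strong in controls and
   weakened in patients and siblings;
2. a graph-structured term (white noise diffused one step along the
   generative adjacency) so that connected regions correlate;
3. a task-evoked term (block boxcar convolved with a canonical double-gamma
   HRF) added to task-positive regions;
4. slow drift, motion- and tissue-driven artefacts, and white noise.

The motion and tissue signals used during generation are returned as the
subject's confound table, so confound regression downstream is exact in
principle.  Everything is deterministic given the cohort seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .connectivity import TimeSeriesMatrix, double_gamma_hrf

__all__ = [
    "CohortSpec",
    "CohortBundle",
    "GroundTruth",
    "generate_topology",
    "generate_component_maps",
    "generate_subject_timeseries",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

GROUPS = ("HC", "SIB", "TLE")

# relative amplitudes of the generative signal ingredients
AMP_COMPONENT = 1.2
AMP_GRAPH = 1.4
AMP_TASK = 0.4
AMP_DRIFT = 0.4
AMP_MOTION = 0.2
AMP_TISSUE = 0.2
GRAPH_DIFFUSION_WEIGHT = 1.0


def _default_task_blocks(n_timepoints: int, tr_seconds: float) -> list:
    """30 s on / 30 s off word-generation-style block design starting at 30 s."""
    blocks = []
    onset = 30.0
    total = n_timepoints * tr_seconds
    while onset + 30.0 <= total:
        blocks.append((onset, 30.0, "task"))
        onset += 60.0
    return blocks


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_controls: int = 30
    n_patients: int = 58
    n_siblings: int = 13
    n_regions: int = 272
    n_timepoints: int = 300
    tr_seconds: float = 1.0
    task_blocks: list = None
    mean_degree: int = 14
    p_rewire: dict = field(default_factory=lambda: {"HC": 0.05, "SIB": 0.20,
                                                    "TLE": 0.28})
    #: between-subject spread of the rewiring parameter on the log scale
    p_rewire_log_sd: float = 1.0
    efnc_coupling: dict = field(default_factory=lambda: {"HC": 0.5, "SIB": 0.1,
                                                         "TLE": 0.1})
    pair_correlation: float = 0.8
    noise_sd: float = 0.5
    #: number of latent network components mixed into the signal; kept below
    #: the analysis-side IC count so ICA has head-room for nuisance structure
    n_components: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "n_siblings", "n_regions",
                     "n_timepoints", "n_components"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_siblings > self.n_patients:
            raise ValueError("n_siblings must be <= n_patients")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for g, p in self.p_rewire.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_rewire[{g}] must lie in [0, 1]")
        if not 0 <= self.pair_correlation <= 1:
            raise ValueError("pair_correlation must lie in [0, 1]")
        if self.task_blocks is None:
            self.task_blocks = _default_task_blocks(self.n_timepoints,
                                                    self.tr_seconds)


@dataclass
class GroundTruth:
    """Generative state of a cohort, for parameter-recovery tests."""

    adjacency: dict          # subject_id -> generative 0/1 adjacency
    p_rewire: dict           # subject_id -> realized rewiring probability
    p_deviation: dict        # subject_id -> latent log-scale deviation z
    coupling: dict           # subject_id -> planted directed coupling a
    component_maps: np.ndarray   # components x regions mixing maps
    source_component: int
    target_component: int
    group_p_rewire: dict
    group_coupling: dict


@dataclass
class CohortBundle:
    spec: CohortSpec
    metadata: pd.DataFrame
    timeseries: dict         # subject_id -> TimeSeriesMatrix
    confounds: dict          # subject_id -> DataFrame
    events: pd.DataFrame
    truth: GroundTruth


def generate_topology(n_regions: int, mean_degree: int, p_rewire: float,
                      seed: int) -> np.ndarray:
    """Watts–Strogatz graph as a dense 0/1 adjacency; guaranteed connected.

    Ring lattice of even degree ``mean_degree`` with each edge rewired
    independently with probability ``p_rewire``.  If the result is
    disconnected the seed is incremented and the draw repeated.  Node
    labels are shuffled so that different draws do not share the ring
    ordering (graph metrics are permutation-invariant; the shuffle only
    removes artificial cross-subject alignment of the lattice).
    """
    if mean_degree % 2 != 0:
        raise ValueError("mean_degree must be even for a ring lattice")
    if mean_degree >= n_regions:
        raise ValueError("mean_degree must be < n_regions")
    if not 0 <= p_rewire <= 1:
        raise ValueError("p_rewire must lie in [0, 1]")
    for attempt in range(100):
        g = nx.watts_strogatz_graph(n_regions, mean_degree, p_rewire,
                                    seed=int(seed) + attempt)
        if nx.is_connected(g):
            adj = nx.to_numpy_array(g, dtype=np.uint8)
            perm = np.random.default_rng(int(seed)).permutation(n_regions)
            return adj[np.ix_(perm, perm)]
    raise RuntimeError("could not draw a connected graph in 100 attempts")


def generate_component_maps(n_components: int, n_regions: int,
                            seed: int) -> np.ndarray:
    """Disjoint component maps (components x regions).

    Regions are partitioned at random among the components (so that no
    component systematically neighbours another on the generative ring
    lattice) and each component loads on its regions with a smooth window
    profile plus small jitter — a cartoon of non-overlapping resting-state
    networks over abstract spatial units.
    """
    rng = np.random.default_rng(seed)
    maps = np.zeros((n_components, n_regions))
    perm = rng.permutation(n_regions)
    edges = np.linspace(0, n_regions, n_components + 1).astype(int)
    for k in range(n_components):
        idx = perm[edges[k]:edges[k + 1]]
        width = idx.size
        profile = np.hanning(width + 2)[1:-1] if width > 1 else np.ones(width)
        maps[k, np.sort(idx)] = profile
    maps += 0.05 * rng.standard_normal(maps.shape)
    return maps


def _smooth_courses(rng: np.random.Generator, n_timepoints: int,
                    n_courses: int, sigma: float = 2.0) -> np.ndarray:
    """Autocorrelated standard-normal time courses (gaussian-smoothed noise)."""
    c = gaussian_filter1d(rng.standard_normal((n_timepoints, n_courses)),
                          sigma=sigma, axis=0, mode="reflect")
    c -= c.mean(axis=0)
    sd = c.std(axis=0)
    sd[sd == 0] = 1.0
    return c / sd


def _task_boxcar(task_blocks, n_timepoints: int, tr: float) -> np.ndarray:
    box = np.zeros(n_timepoints)
    for onset, duration, _cond in task_blocks:
        a = int(np.floor(onset / tr))
        b = int(np.ceil((onset + duration) / tr))
        box[a:min(b, n_timepoints)] = 1.0
    return box


def generate_subject_timeseries(adjacency: np.ndarray, task_blocks,
                                component_maps: np.ndarray,
                                coupling: float, noise_sd: float,
                                tr_seconds: float, n_timepoints: int,
                                seed: int,
                                source_component: int = 0,
                                target_component: int = 1,
                                ) -> tuple[TimeSeriesMatrix, pd.DataFrame]:
    """One subject's BOLD-like time series plus its confound table."""
    a = np.asarray(adjacency, dtype=float)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must be hollow")
    n_regions = a.shape[0]
    rng = np.random.default_rng(seed)
    t = n_timepoints

    # (i) latent component courses with the planted directed coupling
    k = component_maps.shape[0]
    courses = _smooth_courses(rng, t, k)
    courses[:, target_component] += coupling * courses[:, source_component]
    y = AMP_COMPONENT * courses @ component_maps

    # (ii) graph-structured covariance by one-step diffusion along adjacency;
    # per-sqrt(degree) weights keep neighbour correlations strong enough for
    # the thresholded correlation graph to track the generative topology
    deg = a.sum(axis=1)
    deg[deg == 0] = 1.0
    base = _smooth_courses(rng, t, n_regions)
    diffused = base + GRAPH_DIFFUSION_WEIGHT * (base @ (a / np.sqrt(deg)))
    diffused /= diffused.std(axis=0)
    y += AMP_GRAPH * diffused

    # (iii) task-evoked response in task-positive regions (first half)
    box = _task_boxcar(task_blocks, t, tr_seconds)
    hrf = double_gamma_hrf(tr_seconds)
    evoked = np.convolve(box, hrf)[:t]
    task_weights = np.zeros(n_regions)
    task_weights[: n_regions // 2] = 1.0
    y += AMP_TASK * np.outer(evoked, task_weights)

    # (iv) drift + motion/tissue artefacts + white noise
    tt = np.linspace(-1, 1, t)
    drift_basis = np.column_stack([tt, np.cos(np.pi * tt)])
    y += AMP_DRIFT * drift_basis @ rng.standard_normal((2, n_regions))

    steps = rng.standard_normal((t, 6)) * np.r_[[0.02] * 3, [0.0004] * 3]
    motion = np.cumsum(steps, axis=0)
    motion_z = (motion - motion.mean(axis=0)) / np.maximum(motion.std(axis=0), 1e-12)
    y += AMP_MOTION * motion_z @ rng.standard_normal((6, n_regions))

    tissue = _smooth_courses(rng, t, 2, sigma=3.0)
    y += AMP_TISSUE * tissue @ rng.standard_normal((2, n_regions))

    y += noise_sd * rng.standard_normal((t, n_regions))

    confounds = pd.DataFrame(
        np.hstack([motion, tissue]),
        columns=[f"motion_{i}" for i in range(6)] + ["tissue_wm", "tissue_csf"])
    ts = TimeSeriesMatrix(values=y, tr_seconds=tr_seconds)
    return ts, confounds


def _draw_covariates(rng: np.random.Generator, group: str) -> dict:
    """Covariates matched on demographics, patients/siblings lower on cognition."""
    rec = {
        "age": float(np.round(rng.normal(29, 8), 1)),
        "sex": "M" if rng.random() < 0.5 else "F",
        "education": float(np.clip(np.round(rng.normal(12, 3)), 3, 20)),
    }
    cog_shift = {"HC": 0.0, "SIB": -2.0, "TLE": -3.0}[group]
    mood_shift = {"HC": 0.0, "SIB": 2.0, "TLE": 7.0}[group]
    rec["moca"] = float(np.clip(np.round(rng.normal(28 + cog_shift, 2)), 10, 30))
    rec["vfc"] = float(np.clip(np.round(rng.normal(24 + 2 * cog_shift, 5)), 0, 50))
    rec["vfp"] = float(np.clip(np.round(rng.normal(34 + 3 * cog_shift, 8)), 0, 80))
    rec["bn"] = float(np.clip(np.round(rng.normal(27 + cog_shift, 3)), 0, 30))
    rec["sas"] = float(np.clip(np.round(rng.normal(38 + mood_shift, 7)), 20, 80))
    rec["sds"] = float(np.clip(np.round(rng.normal(39 + mood_shift, 8)), 20, 80))
    return rec


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None
                    ) -> CohortBundle:
    """Draw the full cohort; optionally write it to ``out_dir`` on the way."""
    rng = np.random.default_rng(spec.seed)
    seeds = np.random.SeedSequence(spec.seed).generate_state(4 * (
        spec.n_controls + spec.n_patients + spec.n_siblings) + 16) % (2 ** 31)
    seed_iter = iter(seeds.tolist())

    maps = generate_component_maps(spec.n_components, spec.n_regions,
                                   seed=next(seed_iter))
    source_component, target_component = 0, 1

    rows = []
    sid_counter = 0

    def new_sid():
        nonlocal sid_counter
        sid_counter += 1
        return f"sub-{sid_counter:03d}"

    patients = [new_sid() for _ in range(spec.n_patients)]
    siblings = [new_sid() for _ in range(spec.n_siblings)]
    controls = [new_sid() for _ in range(spec.n_controls)]

    # per-subject rewiring parameters: group base scaled by a log-normal
    # deviation; a sibling's deviation is correlated with the paired
    # patient's at pair_correlation
    rho = spec.pair_correlation
    z_pat = rng.standard_normal(spec.n_patients)
    z_sib = rho * z_pat[: spec.n_siblings] + np.sqrt(max(0.0, 1 - rho ** 2)) \
        * rng.standard_normal(spec.n_siblings)
    z_hc = rng.standard_normal(spec.n_controls)

    def realize_p(base, z):
        return float(np.clip(base * np.exp(spec.p_rewire_log_sd * z),
                             0.005, 0.995))

    p_map, z_map, coupling_map, group_map, pair_map = {}, {}, {}, {}, {}
    for i, sid in enumerate(patients):
        group_map[sid] = "TLE"
        z_map[sid] = float(z_pat[i])
        p_map[sid] = realize_p(spec.p_rewire["TLE"], z_pat[i])
        coupling_map[sid] = spec.efnc_coupling["TLE"]
        pair_map[sid] = f"pair-{i + 1:03d}" if i < spec.n_siblings else None
    for i, sid in enumerate(siblings):
        group_map[sid] = "SIB"
        z_map[sid] = float(z_sib[i])
        p_map[sid] = realize_p(spec.p_rewire["SIB"], z_sib[i])
        coupling_map[sid] = spec.efnc_coupling["SIB"]
        pair_map[sid] = f"pair-{i + 1:03d}"
    for i, sid in enumerate(controls):
        group_map[sid] = "HC"
        z_map[sid] = float(z_hc[i])
        p_map[sid] = realize_p(spec.p_rewire["HC"], z_hc[i])
        coupling_map[sid] = spec.efnc_coupling["HC"]
        pair_map[sid] = None

    adjacency, timeseries, confounds = {}, {}, {}
    for sid in patients + siblings + controls:
        group = group_map[sid]
        adj = generate_topology(spec.n_regions, spec.mean_degree,
                                p_map[sid], seed=next(seed_iter))
        adjacency[sid] = adj
        ts, conf = generate_subject_timeseries(
            adj, spec.task_blocks, maps, coupling_map[sid], spec.noise_sd,
            spec.tr_seconds, spec.n_timepoints, seed=next(seed_iter),
            source_component=source_component,
            target_component=target_component)
        timeseries[sid] = ts
        confounds[sid] = conf

        rec = {"subject_id": sid, "group": group, "pair_id": pair_map[sid]}
        rec.update(_draw_covariates(rng, group))
        if group == "TLE":
            rec["subgroup"] = (("HS" if rng.random() < 0.55 else "NHS")
                               + "-" + ("L" if rng.random() < 0.45 else "R"))
            rec["aoo"] = float(np.clip(np.round(rng.normal(17, 7)), 1, 60))
            rec["duration"] = float(np.clip(np.round(rng.normal(11, 7)), 1, 40))
            rec["seizure_frequency"] = int(rng.integers(1, 5))
            rec["n_asms"] = int(rng.integers(1, 4))
            rec["hippocampal_volume"] = float(np.round(rng.normal(0.92, 0.08), 4))
        else:
            rec["subgroup"] = None
            rec["aoo"] = rec["duration"] = np.nan
            rec["seizure_frequency"] = rec["n_asms"] = np.nan
            rec["hippocampal_volume"] = float(np.round(rng.normal(1.0, 0.05), 4))
        rows.append(rec)

    metadata = pd.DataFrame(rows)
    events = pd.DataFrame(spec.task_blocks,
                          columns=["onset", "duration", "trial_type"])
    truth = GroundTruth(adjacency=adjacency, p_rewire=p_map,
                        p_deviation=z_map,
                        coupling=coupling_map, component_maps=maps,
                        source_component=source_component,
                        target_component=target_component,
                        group_p_rewire=dict(spec.p_rewire),
                        group_coupling=dict(spec.efnc_coupling))
    bundle = CohortBundle(spec=spec, metadata=metadata, timeseries=timeseries,
                          confounds=confounds, events=events, truth=truth)
    if out_dir is not None:
        write_cohort(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# on-disk interchange formats (all plain text)

def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    bundle.metadata.to_csv(out / "participants.csv", index=False)
    bundle.events.to_csv(out / "events.tsv", sep="\t", index=False)
    spec_dict = asdict(bundle.spec)
    (out / "cohort_spec.json").write_text(json.dumps(spec_dict, indent=2))
    for sid, ts in bundle.timeseries.items():
        np.savetxt(out / "subjects" / f"{sid}_timeseries.tsv", ts.values,
                   delimiter="\t", fmt="%.8g")
        sidecar = {"tr_seconds": ts.tr_seconds,
                   "region_labels": list(ts.region_labels)}
        (out / "subjects" / f"{sid}_timeseries.json").write_text(
            json.dumps(sidecar))
        bundle.confounds[sid].to_csv(out / "subjects" / f"{sid}_confounds.tsv",
                                     sep="\t", index=False,
                                     float_format="%.8g")
        np.savetxt(out / "truth" / f"{sid}_adjacency.tsv",
                   bundle.truth.adjacency[sid], delimiter="\t", fmt="%d")
    np.savetxt(out / "truth" / "component_maps.tsv",
               bundle.truth.component_maps, delimiter="\t", fmt="%.8g")
    truth_meta = {
        "p_rewire": bundle.truth.p_rewire,
        "p_deviation": bundle.truth.p_deviation,
        "coupling": bundle.truth.coupling,
        "source_component": bundle.truth.source_component,
        "target_component": bundle.truth.target_component,
        "group_p_rewire": bundle.truth.group_p_rewire,
        "group_coupling": bundle.truth.group_coupling,
    }
    (out / "truth" / "ground_truth.json").write_text(
        json.dumps(truth_meta, indent=2))
    return out


def load_cohort(path: str | Path) -> CohortBundle:
    path = Path(path)
    spec_dict = json.loads((path / "cohort_spec.json").read_text())
    if spec_dict.get("task_blocks"):
        spec_dict["task_blocks"] = [tuple(b) for b in spec_dict["task_blocks"]]
    spec = CohortSpec(**spec_dict)
    metadata = pd.read_csv(path / "participants.csv")
    events = pd.read_csv(path / "events.tsv", sep="\t")
    truth_meta = json.loads((path / "truth" / "ground_truth.json").read_text())
    maps = np.loadtxt(path / "truth" / "component_maps.tsv", delimiter="\t",
                      ndmin=2)
    timeseries, confounds, adjacency = {}, {}, {}
    for sid in metadata["subject_id"]:
        sidecar = json.loads(
            (path / "subjects" / f"{sid}_timeseries.json").read_text())
        values = np.loadtxt(path / "subjects" / f"{sid}_timeseries.tsv",
                            delimiter="\t", ndmin=2)
        timeseries[sid] = TimeSeriesMatrix(
            values=values, tr_seconds=sidecar["tr_seconds"],
            region_labels=sidecar["region_labels"])
        confounds[sid] = pd.read_csv(
            path / "subjects" / f"{sid}_confounds.tsv", sep="\t")
        adj_file = path / "truth" / f"{sid}_adjacency.tsv"
        if adj_file.exists():
            adjacency[sid] = np.loadtxt(adj_file, delimiter="\t",
                                        ndmin=2).astype(np.uint8)
    truth = GroundTruth(adjacency=adjacency,
                        p_rewire=truth_meta["p_rewire"],
                        p_deviation=truth_meta["p_deviation"],
                        coupling=truth_meta["coupling"],
                        component_maps=maps,
                        source_component=truth_meta["source_component"],
                        target_component=truth_meta["target_component"],
                        group_p_rewire=truth_meta["group_p_rewire"],
                        group_coupling=truth_meta["group_coupling"])
    return CohortBundle(spec=spec, metadata=metadata, timeseries=timeseries,
                        confounds=confounds, events=events, truth=truth)
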