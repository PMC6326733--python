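"""Multilevel case-control simulation of subject-level FC matrices.

Each simulated edge between nodes ``i`` and ``j`` for subject ``s`` is

    r_ijs = w_ij + g_ijs + alpha_ijs + e_ijs,      g_ijs = b_s + u_ijs

where ``w_ij`` is the groundtruth edge, ``b_s ~ N(0, sigma_b)`` is the
subject's global FC offset (between-person variation in mean FC),
``u_ijs ~ N(0, sigma_w)`` is within-person edgewise variation around that
offset, and ``e_ijs ~ N(0, sigma_e)`` is residual edge noise. Group effects
enter through node-targeted shifts

    alpha_ijs = a_is + v_ijs,   a_is ~ N(mu_a, sigma_a),  v_ijs ~ N(0, sigma_v)

applied to the edges incident to a targeted node, for subjects in the
manipulated group only. When both endpoints of an edge are targeted the
shift is applied exactly once (no compounding): target nodes are visited in
ascending index order and an edge that has already received a shift is
skipped by later nodes and later manipulations.

Default noise levels
--------------------
The between-person SD is ``sigma_b = 0.125``, calibrated in closed form
against the behaviour of weighted (unthresholded) strength analyses: with
negative edges discarded, the two-sample t statistic for a node whose
edges are shifted by ``mu`` is approximately ``mu / (sqrt(2/n) * sigma_b)``
because the ``b_s`` term dominates the between-subject variance of nodal
strength (the edgewise terms average out across ~N edges). At ``n = 50``
per group this puts a +0.14 shift at t ~ 5.5 (clearly detected) and a
-0.04 shift at t ~ -1.6 (mean p ~ .19, nonsignificant), the regime the
whack-a-node experiment requires. The edgewise components are
``sigma_w = sigma_e = 0.2``, the scale single-session FC edge estimates
actually fluctuate at (individual-edge test-retest reliability is poor);
they control how sharply proportional-threshold ranking responds to a
mean shift. Node-shift SDs default to half the mean shift
(``sigma_a = sigma_v = |mu|/2``), the convention the module-targeted
design states explicitly. See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .groundtruth import ConfigurationError, GroundTruthMatrix

__all__ = [
    "NoiseParams",
    "NodeManipulation",
    "ExperimentDesign",
    "SubjectMatrix",
    "Cohort",
    "DesignError",
    "CalibrationError",
    "CalibrationResult",
    "simulate_subject",
    "simulate_cohort",
    "export_cohort",
    "make_whack_design",
    "make_module_design",
    "calibrate_negative_shift",
]

CLIP_LIMIT = 0.999  # shifted correlations are clipped to [-CLIP_LIMIT, CLIP_LIMIT]


class DesignError(ValueError):
    """Structurally invalid experiment design."""


class CalibrationError(RuntimeError):
    """The shift calibration search failed; carries the evaluation trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class NoiseParams:
    """Unsystematic variance components, in correlation units."""

    sigma_b: float = 0.125  # between-person SD of mean FC
    sigma_w: float = 0.20   # within-person edgewise SD around b_s
    sigma_e: float = 0.20   # residual edge noise SD

    def __post_init__(self):
        if min(self.sigma_b, self.sigma_w, self.sigma_e) < 0:
            raise ConfigurationError("noise SDs must be non-negative")


@dataclass(frozen=True)
class NodeManipulation:
    """A group-targeted FC shift on the edges incident to a node set."""

    target_nodes: tuple[int, ...]
    mu_a: float
    sigma_a: float = 0.02
    sigma_v: float = 0.05
    group: str = "patient"
    mode: str = "additive"          # additive | proportional
    edge_scope: str = "all"         # all | within | between
    # whether v_ijs varies per edge or per neighbor module (one draw shared
    # by all of node i's edges into a given foreign module)
    v_granularity: str = "edge"     # edge | module
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "target_nodes", tuple(int(i) for i in self.target_nodes))
        if self.sigma_a < 0 or self.sigma_v < 0:
            raise ConfigurationError("shift SDs must be non-negative")
        if self.mode not in ("additive", "proportional"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.edge_scope not in ("all", "within", "between"):
            raise ConfigurationError(f"unknown edge_scope {self.edge_scope!r}")
        if self.v_granularity not in ("edge", "module"):
            raise ConfigurationError(f"unknown v_granularity {self.v_granularity!r}")
        if len(set(self.target_nodes)) != len(self.target_nodes):
            raise DesignError("duplicate target nodes within a manipulation")


@dataclass(frozen=True)
class ExperimentDesign:
    """Everything that determines one replication sample."""

    n_patients: int = 50
    n_controls: int = 50
    noise: NoiseParams = field(default_factory=NoiseParams)
    manipulations: tuple[NodeManipulation, ...] = ()
    n_replications: int = 100
    seed: int = 0
    node_classes: dict = field(default_factory=dict)  # label -> node index array

    def __post_init__(self):
        object.__setattr__(self, "manipulations", tuple(self.manipulations))
        if self.n_patients < 2 or self.n_controls < 2:
            raise DesignError("need at least 2 subjects per group")
        if self.n_replications < 1:
            raise DesignError("n_replications must be >= 1")
        # manipulations in one group may share nodes only with complementary
        # (within vs between) edge scopes; otherwise their edge sets overlap
        by_group: dict[str, list[NodeManipulation]] = {}
        for man in self.manipulations:
            by_group.setdefault(man.group, []).append(man)
        for group, mans in by_group.items():
            for a in range(len(mans)):
                for b in range(a + 1, len(mans)):
                    shared = set(mans[a].target_nodes) & set(mans[b].target_nodes)
                    scopes = {mans[a].edge_scope, mans[b].edge_scope}
                    if shared and scopes != {"within", "between"}:
                        raise DesignError(
                            f"manipulations for group {group!r} share target nodes "
                            f"{sorted(shared)} with overlapping edge scopes"
                        )


@dataclass(frozen=True)
class SubjectMatrix:
    """One simulated subject-level adjacency matrix."""

    values: np.ndarray
    group: str
    subject_id: str
    b_s: float

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class Cohort:
    """All subjects of one replication sample.

    Edge values are stored condensed (upper triangle, ``M = N(N-1)/2`` per
    subject); :attr:`subjects` materializes full symmetric matrices.
    """

    edge_values: np.ndarray        # (n_subjects, M)
    groups: np.ndarray             # (n_subjects,) of "patient"/"control"
    b_s: np.ndarray                # (n_subjects,)
    design: ExperimentDesign
    replication_id: int
    n_nodes: int
    n_clipped: int = 0

    @property
    def n_subjects(self) -> int:
        return self.edge_values.shape[0]

    @property
    def is_patient(self) -> np.ndarray:
        return self.groups == "patient"

    def matrix(self, s: int) -> np.ndarray:
        """Full symmetric matrix of subject ``s`` (unit diagonal)."""
        n = self.n_nodes
        m = np.eye(n)
        iu = np.triu_indices(n, k=1)
        m[iu] = self.edge_values[s]
        m[(iu[1], iu[0])] = self.edge_values[s]
        return m

    @property
    def subjects(self) -> list[SubjectMatrix]:
        return [
            SubjectMatrix(
                values=self.matrix(s),
                group=str(self.groups[s]),
                subject_id=f"r{self.replication_id:03d}s{s:03d}",
                b_s=float(self.b_s[s]),
            )
            for s in range(self.n_subjects)
        ]


# ---------------------------------------------------------------------------
# compiled manipulation plans


def _condensed_index(n: int):
    """Row/col node indices for the condensed upper-triangle layout."""
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def _pair_to_condensed(n: int):
    """(i, j) -> condensed index lookup table."""
    idx = np.full((n, n), -1, dtype=np.int64)
    iu, ju = _condensed_index(n)
    idx[iu, ju] = np.arange(iu.size)
    idx[ju, iu] = np.arange(iu.size)
    return idx


def _compile_manipulations(groundtruth: GroundTruthMatrix, design: ExperimentDesign):
    """Resolve every manipulation into per-node condensed edge index arrays.

    Applies the no-compounding rule at compile time: nodes are visited in
    ascending order within a manipulation and manipulations in declared
    order; an edge already claimed (per group) is dropped from later claims.
    """
    n = groundtruth.n_nodes
    w = groundtruth.values
    part = groundtruth.partition.assignments
    lookup = _pair_to_condensed(n)
    m_edges = n * (n - 1) // 2
    plans: dict[str, list] = {}
    claimed: dict[str, np.ndarray] = {}
    for man in design.manipulations:
        if max(man.target_nodes, default=-1) >= n:
            raise DesignError(f"target node {max(man.target_nodes)} out of range (N={n})")
        group_claimed = claimed.setdefault(man.group, np.zeros(m_edges, dtype=bool))
        plan = plans.setdefault(man.group, [])
        for i in sorted(man.target_nodes):
            others = np.setdiff1d(np.arange(n), [i])
            if man.edge_scope == "within":
                others = others[part[others] == part[i]]
            elif man.edge_scope == "between":
                others = others[part[others] != part[i]]
            edges = lookup[i, others]
            keep = ~group_claimed[edges]
            edges, others = edges[keep], others[keep]
            group_claimed[edges] = True
            if edges.size == 0:
                continue
            if man.mode == "proportional":
                # multiplicative perturbation w * (1 + s) with s scaled so the
                # expected |change| at an average-strength edge matches the
                # additive shift; zero-strength edges stay unshifted
                mean_abs = np.abs(w[i, others]).mean()
                scale = w[i, others] / mean_abs if mean_abs > 0 else np.zeros(others.size)
            else:
                scale = np.ones(others.size)
            if man.v_granularity == "module":
                # one v draw per neighbor module, shared by its edges
                _, vgroups = np.unique(part[others], return_inverse=True)
            else:
                vgroups = np.arange(others.size)
            plan.append(
                (edges, scale, man.mu_a, man.sigma_a, man.sigma_v,
                 vgroups, int(vgroups.max()) + 1 if vgroups.size else 0)
            )
    return plans


# ---------------------------------------------------------------------------
# simulation


def _draw_subject_edges(w_cond, noise: NoiseParams, plan, rng):
    """Condensed edge vector for one subject. Returns (edges, b_s, n_clipped)."""
    m = w_cond.size
    b_s = rng.normal(0.0, noise.sigma_b) if noise.sigma_b > 0 else 0.0
    r = w_cond + b_s
    if noise.sigma_w > 0:
        r = r + rng.normal(0.0, noise.sigma_w, m)
    for edges, scale, mu_a, sigma_a, sigma_v, vgroups, n_vdraws in plan:
        a_is = rng.normal(mu_a, sigma_a) if sigma_a > 0 else mu_a
        if sigma_v > 0:
            v = rng.normal(0.0, sigma_v, n_vdraws)[vgroups]
        else:
            v = 0.0
        r[edges] += (a_is + v) * scale
    if noise.sigma_e > 0:
        r = r + rng.normal(0.0, noise.sigma_e, m)
    clipped = int(np.count_nonzero(np.abs(r) > CLIP_LIMIT))
    if clipped:
        np.clip(r, -CLIP_LIMIT, CLIP_LIMIT, out=r)
    return r, float(b_s), clipped


def simulate_subject(
    groundtruth: GroundTruthMatrix,
    design: ExperimentDesign,
    group: str,
    rng: np.random.Generator,
) -> SubjectMatrix:
    """Simulate one subject of the given group under the design."""
    n = groundtruth.n_nodes
    iu = np.triu_indices(n, k=1)
    plans = _compile_manipulations(groundtruth, design)
    r, b_s, _ = _draw_subject_edges(
        groundtruth.values[iu], design.noise, plans.get(group, []), rng
    )
    m = np.eye(n)
    m[iu] = r
    m[(iu[1], iu[0])] = r
    return SubjectMatrix(values=m, group=group, subject_id="s000", b_s=b_s)


def simulate_cohort(
    groundtruth: GroundTruthMatrix,
    design: ExperimentDesign,
    replication_id: int = 0,
) -> Cohort:
    """Simulate a full patient + control cohort for one replication.

    The RNG substream is keyed on ``(design.seed, replication_id, subject)``
    so any replication (and any subject in it) is independently
    re-creatable and results do not depend on execution order.
    """
    n = groundtruth.n_nodes
    w_cond = groundtruth.values[np.triu_indices(n, k=1)]
    plans = _compile_manipulations(groundtruth, design)
    groups = np.array(
        ["patient"] * design.n_patients + ["control"] * design.n_controls, dtype=object
    )
    edge_values = np.empty((groups.size, w_cond.size))
    b_all = np.empty(groups.size)
    n_clipped = 0
    for s, group in enumerate(groups):
        rng = substream(design.seed, 0x5B, replication_id, s)
        edge_values[s], b_all[s], c = _draw_subject_edges(
            w_cond, design.noise, plans.get(group, []), rng
        )
        n_clipped += c
    return Cohort(
        edge_values=edge_values,
        groups=groups,
        b_s=b_all,
        design=design,
        replication_id=replication_id,
        n_nodes=n,
        n_clipped=n_clipped,
    )


def export_cohort(cohort: Cohort, directory) -> "pd.DataFrame":
    """Write one dense TSV matrix per subject plus a manifest TSV.

    The manifest (``manifest.tsv``) has columns subject_id, group, file,
    b_s and is returned as a DataFrame.
    """
    import pandas as pd

    from .groundtruth import save_matrix

    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in range(cohort.n_subjects):
        subject_id = f"r{cohort.replication_id:03d}s{s:03d}"
        fname = f"{subject_id}.tsv"
        save_matrix(cohort.matrix(s), directory / fname)
        rows.append({
            "subject_id": subject_id,
            "group": str(cohort.groups[s]),
            "file": fname,
            "b_s": float(cohort.b_s[s]),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# canned designs


def make_whack_design(
    groundtruth: GroundTruthMatrix,
    shift_positive: float = 0.14,
    shift_negative: float = -0.04,
    n_each: int = 3,
    flipped: bool = False,
    proportional: bool = False,
    seed: int = 0,
    *,
    n_patients: int = 50,
    n_controls: int = 50,
    noise: NoiseParams | None = None,
    sigma_a: float | None = None,
    sigma_v: float | None = None,
    n_replications: int = 100,
) -> ExperimentDesign:
    """Design for one whack-a-node replication sample.

    Draws disjoint Positive, Negative and Comparator node sets (``n_each``
    nodes each) uniformly at random from ``seed``; patients receive a
    ``shift_positive`` FC increase on Positive-node edges and a weak
    ``shift_negative`` decrease on Negative-node edges. Comparator nodes are
    recorded but not manipulated. ``flipped`` swaps the shift signs (robust
    hypoconnectivity + weak hyperconnectivity); ``proportional`` applies the
    shifts proportionate to groundtruth edge strength instead of additively.
    Shift SDs default to half the mean shift magnitude (the convention used
    by the module-targeted design). Node sets are meant to be redrawn each
    replication: pass a per-replication seed.
    """
    n = groundtruth.n_nodes
    if 3 * n_each > n:
        raise DesignError(f"3 * n_each = {3 * n_each} exceeds N = {n}")
    rng = substream(seed, 0xDE)
    picks = rng.choice(n, size=3 * n_each, replace=False)
    pos, neg, comp = picks[:n_each], picks[n_each : 2 * n_each], picks[2 * n_each :]
    mode = "proportional" if proportional else "additive"
    sp, sn = (-shift_positive, -shift_negative) if flipped else (shift_positive, shift_negative)
    manips = (
        NodeManipulation(
            target_nodes=tuple(pos), mu_a=sp,
            sigma_a=abs(sp) / 2 if sigma_a is None else sigma_a,
            sigma_v=abs(sp) / 2 if sigma_v is None else sigma_v,
            group="patient", mode=mode, label="Positive",
        ),
        NodeManipulation(
            target_nodes=tuple(neg), mu_a=sn,
            sigma_a=abs(sn) / 2 if sigma_a is None else sigma_a,
            sigma_v=abs(sn) / 2 if sigma_v is None else sigma_v,
            group="patient", mode=mode, label="Negative",
        ),
    )
    return ExperimentDesign(
        n_patients=n_patients,
        n_controls=n_controls,
        noise=noise or NoiseParams(),
        manipulations=manips,
        n_replications=n_replications,
        seed=seed,
        node_classes={
            "Positive": np.sort(pos),
            "Negative": np.sort(neg),
            "Comparator": np.sort(comp),
        },
    )


def make_module_design(
    groundtruth: GroundTruthMatrix,
    seed: int = 0,
    *,
    n_patients: int = 50,
    n_controls: int = 50,
    noise: NoiseParams | None = None,
    mu_between: float = 0.2,
    sigma_a_between: float = 0.1,
    sigma_v_between: float = 0.1,
    mu_within: float = 0.1,
    sigma_a_within: float = 0.05,
    sigma_v_within: float = 0.05,
    n_replications: int = 100,
) -> ExperimentDesign:
    """Design for the global-insensitivity experiment.

    Controls get increased FC on edges between FPN/DAN nodes and other
    networks (mean shift 0.2, between-person SD 0.1, within-person SD 0.1)
    and on edges within the FPN and DAN (mean 0.1, SDs 0.05/0.05); patients
    get the same two-tier structure on DMN nodes. The Visual module is left
    untouched as a comparator.
    """
    part = groundtruth.partition
    for label in ("FPN", "DAN", "DMN", "Visual"):
        if label not in part.module_names:
            raise DesignError(f"partition is missing required module {label!r}")
    fpn_dan = tuple(np.concatenate([part.nodes_of("FPN"), part.nodes_of("DAN")]))
    dmn = tuple(part.nodes_of("DMN"))
    manips = (
        NodeManipulation(fpn_dan, mu_between, sigma_a_between, sigma_v_between,
                         group="control", edge_scope="between", v_granularity="module",
                         label="FPN+DAN between"),
        NodeManipulation(fpn_dan, mu_within, sigma_a_within, sigma_v_within,
                         group="control", edge_scope="within", label="FPN+DAN within"),
        NodeManipulation(dmn, mu_between, sigma_a_between, sigma_v_between,
                         group="patient", edge_scope="between", v_granularity="module",
                         label="DMN between"),
        NodeManipulation(dmn, mu_within, sigma_a_within, sigma_v_within,
                         group="patient", edge_scope="within", label="DMN within"),
    )
    return ExperimentDesign(
        n_patients=n_patients,
        n_controls=n_controls,
        noise=noise or NoiseParams(),
        manipulations=manips,
        n_replications=n_replications,
        seed=seed,
        node_classes={m: part.nodes_of(m) for m in ("DMN", "FPN", "DAN", "Visual")},
    )


@dataclass(frozen=True)
class CalibrationResult:
    shift: float
    achieved_mean_p: float
    sd_p: float
    trace: tuple  # (shift, mean_p) evaluations in order


def _weighted_negative_mean_p(groundtruth, template, shift, n_replications, seed):
    """Mean p of weighted-strength tests at Negative nodes across replications."""
    from scipy import stats as sps

    n = groundtruth.n_nodes
    iu, ju = _condensed_index(n)
    ps = []
    for rep in range(n_replications):
        design = make_whack_design(
            groundtruth,
            shift_positive=template["shift_positive"],
            shift_negative=shift,
            n_each=template["n_each"],
            seed=int(seed + rep),
            n_patients=template["n_patients"],
            n_controls=template["n_controls"],
            noise=template["noise"],
            n_replications=1,
        )
        cohort = simulate_cohort(groundtruth, design, replication_id=0)
        pos_part = np.clip(cohort.edge_values, 0, None)  # negative edges discarded
        strength = np.zeros((cohort.n_subjects, n))
        np.add.at(strength.T, iu, pos_part.T)
        np.add.at(strength.T, ju, pos_part.T)
        pat = strength[cohort.is_patient]
        con = strength[~cohort.is_patient]
        neg = design.node_classes["Negative"]
        t, p = sps.ttest_ind(pat[:, neg], con[:, neg], equal_var=False)
        ps.extend(p.tolist())
    return float(np.mean(ps)), float(np.std(np.asarray(ps).reshape(n_replications, -1).mean(axis=1), ddof=1))


def calibrate_negative_shift(
    groundtruth: GroundTruthMatrix,
    design_template: dict | None = None,
    target_mean_p: float = 0.19,
    tolerance: float = 0.02,
    max_iter: int = 25,
    *,
    n_replications: int = 30,
    seed: int = 0,
    bracket: tuple[float, float] = (0.0, 0.12),
) -> CalibrationResult:
    """Find the Negative-shift magnitude whose weighted-strength tests are
    nonsignificant at the target mean p.

    Bisection on the shift magnitude: the replication-averaged p of
    two-sample strength tests at Negative nodes decreases monotonically in
    |shift| (from ~0.5 at zero shift), so the target mean p identifies a
    unique magnitude. Candidates are evaluated on a reduced replication set
    with common random numbers so the search is smooth and deterministic.
    """
    if not (0 < target_mean_p < 1):
        raise ConfigurationError("target_mean_p must be in (0, 1)")
    template = {
        "shift_positive": 0.14,
        "n_each": 3,
        "n_patients": 50,
        "n_controls": 50,
        "noise": NoiseParams(),
    }
    template.update(design_template or {})
    lo, hi = bracket  # magnitudes; mean_p(lo) should be > target > mean_p(hi)
    trace = []

    def evaluate(mag):
        mean_p, sd_p = _weighted_negative_mean_p(
            groundtruth, template, -abs(mag), n_replications, seed
        )
        trace.append((-abs(mag), mean_p))
        return mean_p, sd_p

    p_lo, _ = evaluate(lo)
    p_hi, sd_hi = evaluate(hi)
    for _ in range(6):
        if p_hi < target_mean_p:
            break
        hi *= 1.5
        p_hi, sd_hi = evaluate(hi)
    if not (p_hi < target_mean_p < p_lo):
        raise CalibrationError(
            f"could not bracket target mean p {target_mean_p} "
            f"(p({lo})={p_lo:.3f}, p({hi})={p_hi:.3f})",
            trace,
        )
    best = (hi, p_hi, sd_hi)
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        p_mid, sd_mid = evaluate(mid)
        if abs(p_mid - target_mean_p) < abs(best[1] - target_mean_p):
            best = (mid, p_mid, sd_mid)
        if abs(p_mid - target_mean_p) <= tolerance:
            return CalibrationResult(
                shift=-mid, achieved_mean_p=p_mid, sd_p=sd_mid, trace=tuple(trace)
            )
        if p_mid > target_mean_p:
            lo = mid
        else:
            hi = mid
    if abs(best[1] - target_mean_p) <= tolerance:
        mag, p_b, sd_b = best
        return CalibrationResult(shift=-mag, achieved_mean_p=p_b, sd_p=sd_b, trace=tuple(trace))
    raise CalibrationError(
        f"calibration did not reach |mean p - {target_mean_p}| <= {tolerance} "
        f"within {max_iter} iterations (best {best[1]:.4f} at shift {-best[0]:.4f})",
        trace,
    )
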