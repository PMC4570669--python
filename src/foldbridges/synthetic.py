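"""Synthetic fold-space inputs with planted, recoverable structure.

This module generates SCOP-like domain hierarchies, multi-method pairwise
alignment-score tables, fold ages and PDB coordinate fixtures.  Everything
downstream (calibration, network construction, community and age analyses)
can therefore be exercised and validated without any external database or
structural aligner.

The generator plants the features the analyses are meant to recover:

* two score populations per pseudo-method — fold siblings versus unrelated
  domain pairs — drawn from truncated normal distributions whose overlap
  controls how well scores discriminate fold membership;
* inter-fold *bridges*: selected cross-fold domain pairs that score like
  siblings.  Each bridge is independently visible to each method with
  probability ``method_agreement``, so a tunable fraction of bridges ends up
  method-unique;
* a five-community organisation of folds (all-alpha, beta-sandwich,
  beta-barrel, alpha/beta, alpha+beta — the all-beta class is split in two)
  that biases where bridges are planted;
* age assortativity on bridges: bridged folds receive similar normalized
  ages, and the more methods that see a bridge the tighter the age match.
  This emulates the empirical pattern that consensus bridges connect folds
  of similar evolutionary age.

One global ``seed`` drives independent child seeds per stage (hierarchy,
bridges, scores, ages, coordinates) so stages can be regenerated alone.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from foldbridges.pairs import all_vs_all_pairs

# child-seed purpose codes (SeedSequence entropy = (seed, code))
_SEED_HIERARCHY = 0
_SEED_BRIDGES = 1
_SEED_SCORES = 2
_SEED_AGES = 3
_SEED_COORDS = 4


def _rng(seed: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, purpose)))


@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to ``[low, high]``.

    Used both to draw synthetic alignment scores and as the closed-form
    reference when checking empirical calibration against analytic cutoffs.
    """

    mu: float
    sigma: float
    low: float = 0.0
    high: float = 1.0

    def _frozen(self):
        a = (self.low - self.mu) / self.sigma
        b = (self.high - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)

    def ppf(self, q):
        return self._frozen().ppf(q)

    def sf(self, x):
        return self._frozen().sf(x)


@dataclass(frozen=True)
class MethodSpec:
    """One pseudo-method: orientation plus its two score populations."""

    name: str
    orientation: str  # "similarity" | "distance"
    sibling: TruncNormal
    unrelated: TruncNormal
    #: emit an additional, noisier score column (exercises AUROC selection)
    secondary_column: str | None = None


def default_methods() -> tuple[MethodSpec, ...]:
    """Four pseudo-methods mirroring the real study's mix.

    Three similarity-oriented methods with TM-score-like ranges (siblings
    around 0.6, unrelated around 0.25) and one distance-oriented method with
    mirrored parameters, so distance handling (sign flip, upper-limit
    cutoffs, reciprocal weights) is always exercised.  One method emits a
    second, weakly informative column so score selection by AUROC has a real
    choice to make.
    """
    sib = TruncNormal(0.60, 0.10)
    unrel = TruncNormal(0.25, 0.08)
    return (
        MethodSpec("simA", "similarity", sib, unrel),
        MethodSpec("simB", "similarity", sib, unrel, secondary_column="aux"),
        MethodSpec("simC", "similarity", sib, unrel),
        MethodSpec("distD", "distance", TruncNormal(0.40, 0.10), TruncNormal(0.75, 0.08)),
    )


def default_community_plan() -> dict[str, str]:
    """Five planted communities over the four SCOP-style classes.

    The all-beta class (b) is split into two communities, emulating the
    empirical separation of beta-sandwiches from beta-barrels.
    """
    return {
        "all-alpha": "a",
        "beta-sandwich": "b",
        "beta-barrel": "b",
        "alpha-beta": "c",
        "alpha-plus-beta": "d",
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic fold-space study.

    Defaults describe the reference study conditions: 4 classes x 16 folds
    with 2-6 domains each (~256 domains, ~33k pairwise comparisons, sibling
    prior ~1%), bridges planted on 20% of inter-fold pairs with 90% of them
    within a planted community, each visible to a given method with
    probability 0.5, and age assortativity 0.05 on bridged folds.
    """

    n_classes: int = 4
    folds_per_class: int = 16
    domains_per_fold: int | tuple[int, int] = (2, 6)
    methods: tuple[MethodSpec, ...] = field(default_factory=default_methods)
    bridge_fraction: float = 0.2
    #: optional cap on a fold's planted-bridge degree; capping fragments the
    #: bridge graph into small components so bridged folds do not all share
    #: one age neighbourhood
    max_bridges_per_fold: int | None = None
    method_agreement: float = 0.5
    within_community_prob: float = 0.9
    #: Gaussian-copula correlation between methods' scores for the same pair
    method_correlation: float = 0.6
    community_plan: dict[str, str] = field(default_factory=default_community_plan)
    #: planted-bridge scores draw from this quantile band of the sibling
    #: distribution: bridges look like weak-to-moderate sibling alignments,
    #: not top-tier ones, so the top of the score scale stays dominated by
    #: true fold siblings and high posterior levels remain attainable.
    #: Set to (0, 1) to draw bridges from the full sibling distribution.
    bridge_quantile_range: tuple[float, float] = (0.02, 0.60)
    age_assortativity: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 1 or self.folds_per_class < 1:
            raise ValueError("n_classes and folds_per_class must be >= 1")
        if self.n_classes > len(string.ascii_lowercase):
            raise ValueError("too many classes for single-letter labels")
        lo, hi = self._domain_range()
        if lo < 1 or hi < lo:
            raise ValueError("domains_per_fold must be >= 1 (or a valid range)")
        for name, value in [
            ("bridge_fraction", self.bridge_fraction),
            ("method_agreement", self.method_agreement),
            ("within_community_prob", self.within_community_prob),
            ("age_assortativity", self.age_assortativity),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not -1.0 < self.method_correlation < 1.0:
            raise ValueError("method_correlation must be in (-1, 1)")
        qlo, qhi = self.bridge_quantile_range
        if not (0.0 <= qlo < qhi <= 1.0):
            raise ValueError("bridge_quantile_range must satisfy 0 <= lo < hi <= 1")
        if not self.methods:
            raise ValueError("at least one method is required")
        if self.max_bridges_per_fold is not None and self.max_bridges_per_fold < 1:
            raise ValueError("max_bridges_per_fold must be >= 1 when set")

    def _domain_range(self) -> tuple[int, int]:
        if isinstance(self.domains_per_fold, int):
            return self.domains_per_fold, self.domains_per_fold
        lo, hi = self.domains_per_fold
        return int(lo), int(hi)

    def class_labels(self) -> list[str]:
        return list(string.ascii_lowercase[: self.n_classes])

    def method_names(self) -> list[str]:
        return [m.name for m in self.methods]


# ---------------------------------------------------------------------------
# hierarchy


def generate_hierarchy(spec: SyntheticSpec) -> pd.DataFrame:
    """Generate a SCOP-style annotation table.

    Returns a frame with columns ``domain_id, family, superfamily, fold,
    class``.  Fold identifiers follow the ``x.N`` convention; superfamily and
    family identifiers nest beneath their fold (``x.N.M``, ``x.N.M.K``).
    """
    spec.validate()
    rng = _rng(spec.seed, _SEED_HIERARCHY)
    lo, hi = spec._domain_range()
    rows = []
    idx = 0
    for cls in spec.class_labels():
        for k in range(1, spec.folds_per_class + 1):
            fold = f"{cls}.{k}"
            n_dom = int(rng.integers(lo, hi + 1))
            # a fold usually holds few superfamilies, each with few families
            sf_of_dom = _nested_labels(rng, n_dom)
            fam_of_dom = np.empty(n_dom, dtype=int)
            for sf in np.unique(sf_of_dom):
                members = np.flatnonzero(sf_of_dom == sf)
                fam_of_dom[members] = _nested_labels(rng, members.size)
            for d in range(n_dom):
                sf = f"{fold}.{sf_of_dom[d] + 1}"
                fam = f"{sf}.{fam_of_dom[d] + 1}"
                rows.append((f"d{idx:05d}", fam, sf, fold, cls))
                idx += 1
    return pd.DataFrame(rows, columns=["domain_id", "family", "superfamily", "fold", "class"])


def _nested_labels(rng: np.random.Generator, n: int, split_prob: float = 0.25) -> np.ndarray:
    """Partition n items into 1 + Binomial(n-1, p) consecutive groups."""
    n_groups = 1 + int(rng.binomial(n - 1, split_prob)) if n > 1 else 1
    labels = rng.integers(0, n_groups, size=n)
    _, relabeled = np.unique(labels, return_inverse=True)
    return relabeled


# ---------------------------------------------------------------------------
# communities and planted bridges


def fold_communities(spec: SyntheticSpec, annotation: pd.DataFrame) -> pd.Series:
    """Map each fold to its planted community label.

    Classes referenced by several communities have their folds split into
    near-equal contiguous blocks, one per community, in plan order.
    """
    folds_by_class: dict[str, list[str]] = {}
    for fold, cls in (
        annotation[["fold", "class"]].drop_duplicates().itertuples(index=False)
    ):
        folds_by_class.setdefault(cls, []).append(fold)
    communities_of_class: dict[str, list[str]] = {}
    for community, cls in spec.community_plan.items():
        communities_of_class.setdefault(cls, []).append(community)
    mapping: dict[str, str] = {}
    for cls, folds in folds_by_class.items():
        names = communities_of_class.get(cls, [f"class-{cls}"])
        chunks = np.array_split(np.asarray(folds, dtype=object), len(names))
        for name, chunk in zip(names, chunks):
            for fold in chunk:
                mapping[fold] = name
    return pd.Series(mapping, name="community")


def plant_bridges(spec: SyntheticSpec, annotation: pd.DataFrame) -> pd.DataFrame:
    """Plant inter-fold bridges, their carrier domain pairs and visibility.

    A fraction ``bridge_fraction`` of all inter-fold pairs is selected as
    bridges; each draw lands within a planted community with probability
    ``within_community_prob``.  Every bridge carries one cross-fold domain
    pair (the pair that will score like siblings) and one independent
    Bernoulli(``method_agreement``) visibility flag per method.
    """
    spec.validate()
    _check_annotation(annotation)
    rng = _rng(spec.seed, _SEED_BRIDGES)
    folds = annotation["fold"].drop_duplicates().to_numpy()
    community = fold_communities(spec, annotation)
    n = folds.size
    i, j = np.triu_indices(n, k=1)
    same = (community[folds[i]].to_numpy() == community[folds[j]].to_numpy())
    n_pairs = i.size
    n_bridges = int(round(spec.bridge_fraction * n_pairs))
    if n_bridges == 0 or n_pairs == 0:
        cols = ["fold_a", "fold_b", "domain_a", "domain_b", "same_community"]
        cols += [f"visible_{m}" for m in spec.method_names()]
        return pd.DataFrame(columns=cols)

    within = np.flatnonzero(same)
    cross = np.flatnonzero(~same)
    n_within = min(int(rng.binomial(n_bridges, spec.within_community_prob)), within.size)
    n_cross = min(n_bridges - n_within, cross.size)
    degree: dict[str, int] = {}
    cap = spec.max_bridges_per_fold

    def accept(candidates: np.ndarray, target: int) -> list[int]:
        taken = []
        for p in rng.permutation(candidates):
            if len(taken) == target:
                break
            fa, fb = folds[i[p]], folds[j[p]]
            if cap is not None and (degree.get(fa, 0) >= cap or degree.get(fb, 0) >= cap):
                continue
            degree[fa] = degree.get(fa, 0) + 1
            degree[fb] = degree.get(fb, 0) + 1
            taken.append(int(p))
        return taken

    chosen = np.array(sorted(accept(within, n_within) + accept(cross, n_cross)), dtype=int)

    domains_of = annotation.groupby("fold", sort=False)["domain_id"].agg(list)
    rows = []
    for p in chosen:
        fa, fb = folds[i[p]], folds[j[p]]
        da = domains_of[fa][rng.integers(len(domains_of[fa]))]
        db = domains_of[fb][rng.integers(len(domains_of[fb]))]
        rows.append((fa, fb, da, db, bool(same[p])))
    out = pd.DataFrame(
        rows, columns=["fold_a", "fold_b", "domain_a", "domain_b", "same_community"]
    )
    visible = rng.random((len(out), len(spec.methods))) < spec.method_agreement
    for m_idx, name in enumerate(spec.method_names()):
        out[f"visible_{name}"] = visible[:, m_idx]
    return out


def _check_annotation(annotation: pd.DataFrame) -> None:
    required = {"domain_id", "family", "superfamily", "fold", "class"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table is missing columns: {sorted(missing)}")
    if annotation["domain_id"].duplicated().any():
        raise ValueError("annotation table has duplicate domain identifiers")


# ---------------------------------------------------------------------------
# score tables


def generate_score_tables(
    spec: SyntheticSpec,
    annotation: pd.DataFrame,
    bridges: pd.DataFrame | None = None,
) -> dict[str, "ScoreTable"]:
    """Draw one pairwise score table per pseudo-method.

    Sibling pairs draw from the method's sibling distribution, unrelated
    pairs from its unrelated distribution — except planted bridge carrier
    pairs, which draw from the sibling distribution in the methods the
    bridge is visible to.  Scores of the same pair are correlated across
    methods through a shared Gaussian-copula latent with per-method noise.
    """
    from foldbridges.calibration import ScoreTable  # deferred: avoids cycle

    spec.validate()
    _check_annotation(annotation)
    if bridges is None:
        bridges = plant_bridges(spec, annotation)
    rng = _rng(spec.seed, _SEED_SCORES)

    ids = annotation["domain_id"].to_numpy()
    folds = annotation["fold"].to_numpy()
    n = ids.size
    i, j = all_vs_all_pairs(ids)
    sibling = folds[i] == folds[j]
    n_pairs = i.size

    id_pos = {d: p for p, d in enumerate(ids)}
    bridge_rows = _bridge_pair_rows(bridges, id_pos, n)

    rho = spec.method_correlation
    latent = rng.standard_normal(n_pairs)
    tables: dict[str, ScoreTable] = {}
    for m_idx, method in enumerate(spec.methods):
        eps = rng.standard_normal(n_pairs)
        q = stats.norm.cdf(rho * latent + np.sqrt(1.0 - rho * rho) * eps)
        q = np.clip(q, 1e-12, 1.0 - 1e-12)
        # q is a similarity quantile; distance methods see it mirrored so a
        # structurally similar pair scores high in every method at once
        flip = method.orientation == "distance"
        qm = 1.0 - q if flip else q
        score = np.where(sibling, method.sibling.ppf(qm), method.unrelated.ppf(qm))
        if len(bridges):
            visible = bridges[f"visible_{method.name}"].to_numpy()
            rows = bridge_rows[visible]
            qlo, qhi = spec.bridge_quantile_range
            band = qlo + (qhi - qlo) * q[rows]
            score[rows] = method.sibling.ppf(1.0 - band if flip else band)
        frame = pd.DataFrame(
            {"domain_i": ids[i], "domain_j": ids[j], "score": score}
        )
        columns = ["score"]
        if method.secondary_column is not None:
            # weakly informative companion column: primary signal + heavy noise
            frame[method.secondary_column] = score + rng.normal(0.0, 0.3, n_pairs)
            columns.append(method.secondary_column)
        tables[method.name] = ScoreTable(
            frame, method=method.name, orientation=method.orientation, score_columns=columns
        )
    return tables


def _bridge_pair_rows(
    bridges: pd.DataFrame, id_pos: dict[str, int], n: int
) -> np.ndarray:
    """Row indices of bridge carrier pairs in the triu pair enumeration."""
    if not len(bridges):
        return np.empty(0, dtype=int)
    a = bridges["domain_a"].map(id_pos)
    b = bridges["domain_b"].map(id_pos)
    if a.isna().any() or b.isna().any():
        raise ValueError("bridge table references domains absent from the annotation")
    a = a.to_numpy(dtype=int)
    b = b.to_numpy(dtype=int)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    # row of pair (lo, hi) in np.triu_indices(n, 1) ordering
    return lo * (n - 1) - lo * (lo - 1) // 2 + (hi - lo - 1)


# ---------------------------------------------------------------------------
# ages


def generate_ages(
    spec: SyntheticSpec,
    annotation: pd.DataFrame,
    bridges: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each fold a normalized age in [0, 1] with planted assortativity.

    Unbridged folds draw uniform ages.  Bridged folds draw a shared
    component centre plus a per-fold offset sized so that every planted
    bridge satisfies ``|age_a - age_b| <= tol`` where
    ``tol = age_assortativity ** (1 + k)`` and ``k`` is the number of
    methods the bridge is visible to.  Consensus bridges therefore connect
    folds of nearly identical age while method-unique bridges are allowed
    the full assortativity budget — the gradient the age analyses are built
    to detect.  Offsets are reflected back into [0, 1], which preserves the
    per-bridge bound.  With ``age_assortativity == 1`` every tolerance is
    vacuous and all ages are independent uniforms; with
    ``age_assortativity == 0`` all folds of a bridged component share a
    single age draw.
    """
    spec.validate()
    rng = _rng(spec.seed, _SEED_AGES)
    folds = annotation["fold"].drop_duplicates().to_numpy()
    delta = spec.age_assortativity

    visible_cols = [c for c in bridges.columns if c.startswith("visible_")]
    if len(bridges):
        k = bridges[visible_cols].to_numpy(dtype=bool).sum(axis=1)
        tol = np.power(delta, 1.0 + k)
    else:
        tol = np.empty(0)

    # tightest incident tolerance bounds each fold's offset amplitude
    amplitude = {f: np.inf for f in folds}
    adjacency: dict[str, set[str]] = {f: set() for f in folds}
    for row, (fa, fb) in enumerate(zip(bridges.get("fold_a", []), bridges.get("fold_b", []))):
        adjacency[fa].add(fb)
        adjacency[fb].add(fa)
        amplitude[fa] = min(amplitude[fa], tol[row] / 2.0)
        amplitude[fb] = min(amplitude[fb], tol[row] / 2.0)

    component = _components(folds, adjacency)
    centers = {}
    ages = np.empty(folds.size)
    for idx, fold in enumerate(folds):
        comp = component[fold]
        if comp not in centers:
            centers[comp] = rng.uniform()
        if amplitude[fold] >= 0.5:
            # unbridged, or every incident tolerance is vacuous: independent uniform
            ages[idx] = rng.uniform()
        else:
            offset = amplitude[fold] * rng.uniform(-1.0, 1.0)
            ages[idx] = _reflect01(centers[comp] + offset)
    return pd.DataFrame({"fold": folds, "age": ages})


def _components(folds: np.ndarray, adjacency: dict[str, set[str]]) -> dict[str, int]:
    comp = {}
    current = 0
    for fold in folds:
        if fold in comp:
            continue
        stack = [fold]
        comp[fold] = current
        while stack:
            u = stack.pop()
            for v in sorted(adjacency[u]):
                if v not in comp:
                    comp[v] = current
                    stack.append(v)
        current += 1
    return comp


def _reflect01(x: float) -> float:
    """Fold a real number into [0, 1] by reflection at the boundaries."""
    x = abs(x) % 2.0
    return 2.0 - x if x > 1.0 else x


def generate_centrality_correlated_ages(
    annotation: pd.DataFrame,
    bridges: pd.DataFrame | None = None,
    seed: int = 0,
    noise_sd: float = 0.05,
    centrality: pd.Series | None = None,
) -> pd.DataFrame:
    """Ages planted to increase with a fold's centrality.

    Used to validate the central-versus-peripheral age comparison: central
    folds receive systematically older ages.  ``centrality`` may be any
    fold-indexed score (e.g. the weighted degree of a constructed network);
    when omitted, the planted-bridge degree is used.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, _SEED_AGES, 1)))
    folds = annotation["fold"].drop_duplicates().to_numpy()
    if centrality is None:
        centrality = pd.Series(0.0, index=folds)
        if bridges is not None:
            for col in ("fold_a", "fold_b"):
                if col in bridges:
                    centrality = centrality.add(bridges[col].value_counts(), fill_value=0.0)
    score = centrality.reindex(folds).fillna(0.0).to_numpy()
    nrank = (stats.rankdata(score) - 1.0) / max(len(folds) - 1, 1)
    age = np.clip(0.1 + 0.8 * nrank + rng.normal(0.0, noise_sd, folds.size), 0.0, 1.0)
    return pd.DataFrame({"fold": folds, "age": age})


# ---------------------------------------------------------------------------
# coordinate fixtures


@dataclass(frozen=True)
class CoordinateFixture:
    name: str
    text: str
    planted_break_index: int | None
    calpha_only: bool


def generate_coordinate_fixtures(
    n_domains: int,
    break_fraction: float,
    calpha_only_fraction: float,
    seed: int,
    out_dir=None,
) -> list[CoordinateFixture]:
    """Emit minimal single-chain PDB files for the QC stage.

    Consecutive C-alpha atoms are ~3.8 A apart except at planted chain
    breaks (> 4.3 A).  A stated fraction of fixtures contains only C-alpha
    atoms.  Returns the fixtures with their planted ground truth; writes
    ``<name>.pdb`` files when ``out_dir`` is given.
    """
    for name, value in [("break_fraction", break_fraction), ("calpha_only_fraction", calpha_only_fraction)]:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, _SEED_COORDS)))
    fixtures = []
    for d in range(n_domains):
        length = int(rng.integers(30, 61))
        spacings = rng.uniform(3.75, 3.85, size=length - 1)
        break_index = None
        if rng.random() < break_fraction and length > 2:
            break_index = int(rng.integers(1, length - 1))
            spacings[break_index] = rng.uniform(4.8, 7.0)
        calpha_only = bool(rng.random() < calpha_only_fraction)
        coords = _chain_coords(rng, spacings)
        name = f"syn{d:04d}"
        text = _pdb_text(coords, calpha_only)
        fixtures.append(CoordinateFixture(name, text, break_index, calpha_only))
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fx in fixtures:
            (out / f"{fx.name}.pdb").write_text(fx.text)
    return fixtures


def _chain_coords(rng: np.random.Generator, spacings: np.ndarray) -> np.ndarray:
    coords = np.zeros((spacings.size + 1, 3))
    for r, gap in enumerate(spacings):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        coords[r + 1] = coords[r] + gap * direction
    return coords


def _pdb_text(coords: np.ndarray, calpha_only: bool) -> str:
    lines = []
    serial = 1
    for res, ca in enumerate(coords, start=1):
        atoms = [("CA", ca, "C")]
        if not calpha_only:
            atoms = [
                ("N", ca + np.array([-1.46, 0.0, 0.0]), "N"),
                ("CA", ca, "C"),
                ("C", ca + np.array([1.52, 0.0, 0.0]), "C"),
                ("O", ca + np.array([1.52, 1.23, 0.0]), "O"),
            ]
        for name, xyz, element in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}ALA A{res:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SyntheticBundle:
    spec: SyntheticSpec
    annotation: pd.DataFrame
    bridges: pd.DataFrame
    score_tables: dict
    ages: pd.DataFrame
    communities: pd.Series


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate the full synthetic input bundle for one spec."""
    annotation = generate_hierarchy(spec)
    bridges = plant_bridges(spec, annotation)
    score_tables = generate_score_tables(spec, annotation, bridges)
    ages = generate_ages(spec, annotation, bridges)
    communities = fold_communities(spec, annotation)
    return SyntheticBundle(spec, annotation, bridges, score_tables, ages, communities)


def strong_community_spec(seed: int = 0) -> SyntheticSpec:
    """Spec with widely separated score populations and full method agreement.

    Intended for community-recovery validation: bridges are dense within the
    five planted communities, every method sees every bridge, and the score
    populations barely overlap so essentially no spurious edges appear.
    """
    sib = TruncNormal(0.80, 0.06)
    unrel = TruncNormal(0.20, 0.06)
    methods = (
        MethodSpec("simA", "similarity", sib, unrel),
        MethodSpec("simB", "similarity", sib, unrel, secondary_column="aux"),
        MethodSpec("simC", "similarity", sib, unrel),
        MethodSpec("distD", "distance", TruncNormal(0.20, 0.06), TruncNormal(0.80, 0.06)),
    )
    return SyntheticSpec(
        folds_per_class=15,
        domains_per_fold=5,
        methods=methods,
        bridge_fraction=0.15,
        method_agreement=1.0,
        seed=seed,
    )


def scaled_spec(seed: int = 0, folds_per_class: int = 56) -> SyntheticSpec:
    """Default score populations scaled up to ~10^5 pairwise comparisons.

    Two representative domains per fold keep the comparison schedule compact
    while every fold still contributes one sibling pair to the calibration.
    """
    return replace(
        SyntheticSpec(seed=seed), folds_per_class=folds_per_class, domains_per_fold=2
    )


def age_study_spec(seed: int = 0) -> SyntheticSpec:
    """Study conditions for the edge-multiplicity / fold-age analyses.

    Close to the real survey's fold count (768 folds, two representative
    domains each, ~1.2M pairwise comparisons).  Bridges are sparse (planted
    on ~0.2% of inter-fold pairs) with at most two bridges per fold, so the
    planted-bridge graph fragments into many small components: bridged folds
    form small same-age neighbourhoods while the unconnected background
    keeps the diversity of independent uniform ages.
    """
    return replace(
        SyntheticSpec(seed=seed),
        folds_per_class=192,
        domains_per_fold=2,
        bridge_fraction=0.0022,
        max_bridges_per_fold=2,
    )
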