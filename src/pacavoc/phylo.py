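"""Phylogenetically independent contrasts over caviomorph rodents.

This module is the comparative engine of the package: it encodes the
caviomorph topology, assigns Nee branch lengths (node height above the tips
equal to log10 of the number of descendant tips, used when true branch
lengths are unknown), computes Felsenstein's standardized independent
contrasts, regresses group-size contrasts on vocal-repertoire contrasts,
and inverts that regression at the focal species' node to back-predict its
group size from its repertoire alone.

Under Brownian trait evolution the standardized contrasts are independent
and identically distributed, which is what licenses ordinary least squares
across species despite shared ancestry.

Notation: at an internal node joining lineages with values ``x1, x2`` and
(adjusted) branch lengths ``b1, b2``, the raw contrast is ``x1 - x2``, the
standardized contrast is ``(x1 - x2) / sqrt(b1 + b2)``, the nodal value is
the precision-weighted mean ``(b2*x1 + b1*x2) / (b1 + b2)``, and the branch
above the node is lengthened by ``b1*b2 / (b1 + b2)`` to absorb the
uncertainty of the nodal estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "Phylogeny",
    "Contrast",
    "ContrastSet",
    "ContrastRegression",
    "GroupSizePrediction",
    "nee_branch_lengths",
    "pic",
    "fit_contrast_regression",
    "predict_group_size",
    "load_caviomorph_tree",
    "load_caviomorph_traits",
    "attach_focal",
    "scan_configurations",
    "FOCAL_SPECIES",
]

FOCAL_SPECIES = "Cuniculus_paca"

#: Documented readings of the focal species' position in the caviomorph
#: topology. "dasyprocta_cherry" (the default) places the paca as sister to
#: Dasyprocta leporina, the usual resolution of Cuniculidae + Dasyproctidae;
#: the alternatives attach it below the cavioid clade or at the root.
ATTACHMENTS = ("dasyprocta_cherry", "cavioid_base", "root")


class PhylogenyError(ValueError):
    """Raised for malformed trees or trait/tree mismatches."""


class Node:
    """A node of a rooted binary phylogeny.

    ``depth`` is the height of the node above the tips; ``length`` is the
    edge length to the parent (``None`` at the root, and before branch
    lengths have been assigned).
    """

    __slots__ = ("label", "children", "length", "depth")

    def __init__(self, label=None, children=None, length=None, depth=None):
        self.label = label
        self.children: list[Node] = list(children) if children else []
        self.length = length
        self.depth = depth

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tip_labels(self) -> tuple[str, ...]:
        if self.is_tip:
            return (self.label,)
        return tuple(l for c in self.children for l in c.tip_labels())

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def copy(self) -> "Node":
        return Node(self.label, [c.copy() for c in self.children], self.length, self.depth)


class Phylogeny:
    """A rooted binary tree with labeled tips."""

    def __init__(self, root: Node):
        self.root = root
        labels = root.tip_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        for node in root.postorder():
            if node.children and len(node.children) != 2:
                raise PhylogenyError(
                    "independent contrasts require a fully binary tree; "
                    f"node with {len(node.children)} children found"
                )

    @property
    def n_tips(self) -> int:
        return len(self.root.tip_labels())

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self.root.tip_labels()

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.root.copy())

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> Node:
            label = None
            if dnode.is_leaf():
                label = dnode.taxon.label.replace(" ", "_") if dnode.taxon else None
            length = dnode.edge.length
            return Node(label, [convert(c) for c in dnode.child_nodes()], length)

        return cls(convert(tree.seed_node))

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                s = node.label
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.length is not None:
                s += f":{node.length:.6f}"
            return s

        return fmt(self.root) + ";"

    def find_tip(self, label: str) -> Node:
        for node in self.root.postorder():
            if node.is_tip and node.label == label:
                return node
        raise PhylogenyError(f"tip {label!r} not in tree")

    def parent_of(self, target: Node) -> Node | None:
        for node in self.root.postorder():
            if target in node.children:
                return node
        return None


def nee_branch_lengths(tree: Phylogeny) -> Phylogeny:
    """Assign Nee branch lengths: node height = log10(number of descendant tips).

    Tips sit at height zero; each edge length is the height difference
    between parent and child. The operation is idempotent and the total
    depth of the tree equals log10 of the tip count. Because every parent
    strictly contains its children's tips, all edge lengths are positive on
    a binary tree.
    """
    out = tree.copy()

    def assign(node: Node) -> None:
        node.depth = 0.0 if node.is_tip else math.log10(len(node.tip_labels()))
        for c in node.children:
            assign(c)
            c.length = node.depth - c.depth
            if c.length <= 0:
                raise PhylogenyError(
                    f"non-positive Nee edge length at node with tips {c.tip_labels()}"
                )

    assign(out.root)
    out.root.length = None
    return out


@dataclass(frozen=True)
class Contrast:
    """One independent contrast at an internal node.

    ``clade`` is the frozenset of tip labels below the node (the stable key
    used to match contrasts between traits); child order in the tree fixes
    the sign of ``raw``.
    """

    clade: frozenset
    raw: float
    denominator: float
    standardized: float
    nodal_value: float
    adjusted_extra: float


class ContrastSet:
    """The n-1 contrasts of one trait on an n-tip tree, in postorder."""

    def __init__(self, contrasts: Sequence[Contrast]):
        self.contrasts = list(contrasts)
        self.by_clade = {c.clade: c for c in self.contrasts}

    def __len__(self) -> int:
        return len(self.contrasts)

    def __iter__(self):
        return iter(self.contrasts)

    @property
    def standardized(self) -> np.ndarray:
        return np.array([c.standardized for c in self.contrasts])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clade": ["|".join(sorted(c.clade)) for c in self.contrasts],
                "raw": [c.raw for c in self.contrasts],
                "denominator": [c.denominator for c in self.contrasts],
                "standardized": [c.standardized for c in self.contrasts],
                "nodal_value": [c.nodal_value for c in self.contrasts],
            }
        )


def _pic_recurse(node: Node, traits: Mapping[str, float], out: list[Contrast]):
    """Return (value, adjusted branch length to parent) below ``node``."""
    if node.is_tip:
        try:
            return float(traits[node.label]), float(node.length)
        except KeyError:
            raise PhylogenyError(f"no trait value for tip {node.label!r}") from None
    (x1, b1), (x2, b2) = (_pic_recurse(c, traits, out) for c in node.children)
    if b1 + b2 <= 0:
        raise PhylogenyError("zero standardization denominator (zero branch lengths)")
    den = math.sqrt(b1 + b2)
    raw = x1 - x2
    nodal = (b2 * x1 + b1 * x2) / (b1 + b2)
    extra = b1 * b2 / (b1 + b2)
    out.append(
        Contrast(frozenset(node.tip_labels()), raw, den, raw / den, nodal, extra)
    )
    parent_edge = node.length if node.length is not None else 0.0
    return nodal, parent_edge + extra


def pic(tree: Phylogeny, traits: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's independent contrasts of one trait on a tree with branch lengths.

    Every tip must carry a trait value and every non-root edge a positive
    length (e.g. from :func:`nee_branch_lengths`). Returns the n-1 contrasts
    in postorder, each carrying its raw contrast, standardizing denominator
    sqrt(b1+b2) on Felsenstein-adjusted branches, nodal (ancestral) value,
    and the branch-length adjustment passed to the parent.
    """
    for node in tree.root.postorder():
        if node is not tree.root and node.length is None:
            raise PhylogenyError("tree has no branch lengths; apply nee_branch_lengths first")
    out: list[Contrast] = []
    _pic_recurse(tree.root, traits, out)
    return ContrastSet(out)


@dataclass
class ContrastRegression:
    """OLS fit of response contrasts on predictor contrasts."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    positivized: bool
    include_intercept: bool
    n_contrasts: int
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    _results: object = field(default=None, repr=False)

    def predict(self, x_new: float) -> float:
        return self.intercept + self.slope * x_new

    def prediction_interval(self, x_new: float, alpha: float = 0.05, kind: str = "prediction"):
        """Interval for a new observation (default) or for the mean response."""
        import statsmodels.api as sm

        exog = np.array([[1.0, x_new]]) if self.include_intercept else np.array([[x_new]])
        pred = self._results.get_prediction(exog)
        frame = pred.summary_frame(alpha=alpha)
        if kind == "prediction":
            lo, hi = float(frame["obs_ci_lower"].iloc[0]), float(frame["obs_ci_upper"].iloc[0])
        elif kind == "mean":
            lo, hi = float(frame["mean_ci_lower"].iloc[0]), float(frame["mean_ci_upper"].iloc[0])
        else:
            raise ValueError(f"unknown interval kind {kind!r}")
        return lo, hi


def fit_contrast_regression(
    x: ContrastSet,
    y: ContrastSet,
    include_intercept: bool = True,
    positivize: bool = True,
) -> ContrastRegression:
    """Regress standardized response contrasts on predictor contrasts.

    ``positivize`` applies the standard comparative-methods sign convention:
    each predictor contrast is reflected to be non-negative and the paired
    response contrast has its sign flipped accordingly (contrast signs are
    arbitrary, set by child order in the tree). With an intercept the fit is
    not invariant to those signs, so the convention matters and is recorded
    on the result.
    """
    import statsmodels.api as sm

    if set(x.by_clade) != set(y.by_clade):
        raise PhylogenyError("contrast sets computed on different trees")
    if len(x) < 3:
        raise PhylogenyError("need at least 3 contrasts to fit a regression line")
    clades = [c.clade for c in x.contrasts]
    xv = np.array([x.by_clade[k].standardized for k in clades])
    yv = np.array([y.by_clade[k].standardized for k in clades])
    if positivize:
        s = np.where(xv < 0, -1.0, 1.0)
        xv, yv = xv * s, yv * s
    if np.allclose(xv.var(), 0):
        raise PhylogenyError("degenerate predictor contrasts (zero variance)")
    exog = sm.add_constant(xv) if include_intercept else xv[:, None]
    res = sm.OLS(yv, exog).fit()
    if include_intercept:
        intercept, slope = res.params
    else:
        intercept, slope = 0.0, res.params[0]
    return ContrastRegression(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)),
        p_value=float(res.f_pvalue),
        positivized=positivize,
        include_intercept=include_intercept,
        n_contrasts=len(xv),
        x=xv,
        y=yv,
        _results=res,
    )


@dataclass
class GroupSizePrediction:
    """Back-prediction of a focal species' group size from its repertoire."""

    x_contrast: float
    y_contrast: float
    log10_group_size: float
    group_size: float
    interval: tuple[float, float]
    interval_kind: str
    attachment: str
    sister_value: float
    denominator: float


def _sister_of(tree: Phylogeny, focal: str) -> tuple[Node, Node, Node]:
    tip = tree.find_tip(focal)
    parent = tree.parent_of(tip)
    if parent is None:
        raise PhylogenyError("focal species cannot be the root")
    sister = parent.children[0] if parent.children[1] is tip else parent.children[1]
    return tip, parent, sister


def predict_group_size(
    reg: ContrastRegression,
    tree_with_focal: Phylogeny,
    repertoire: Mapping[str, float],
    group_size: Mapping[str, float],
    focal: str = FOCAL_SPECIES,
    interval: str = "prediction",
    alpha: float = 0.05,
) -> GroupSizePrediction:
    """Invert the contrasts regression at the focal node.

    The focal species' standardized predictor contrast ``x`` is computed
    against its sister lineage (whose nodal value and Felsenstein-adjusted
    branch length come from the usual recursion over the sister subtree);
    the regression predicts the paired response contrast; and the contrast
    standardization is inverted -- response nodal value of the sister plus
    predicted contrast times the standardizing denominator -- to recover the
    focal species' log10 group size, which is then exponentiated. The
    regression's 95% interval (for a new observation by default, for the
    mean response with ``interval="mean"``) propagates through the same
    affine inversion.

    ``repertoire`` must cover every tip (log10 values); ``group_size`` must
    cover every tip except the focal one.
    """
    if focal in group_size:
        raise PhylogenyError(f"{focal!r} must not have a group-size value (it is predicted)")
    tip, parent, sister = _sister_of(tree_with_focal, focal)
    b_focal = tip.length

    dummy: list[Contrast] = []
    x_sis, bx_sis = _pic_recurse(sister, repertoire, dummy)
    y_sis, by_sis = _pic_recurse(sister, group_size, dummy)
    # the sister subtree is identical for both traits, so the adjusted
    # branch lengths agree; use the x side.
    den = math.sqrt(b_focal + bx_sis)
    x_focal = float(repertoire[focal])
    x_c = (x_focal - x_sis) / den

    # respect the regression's sign convention: a negative predictor
    # contrast is reflected for prediction and the predicted response
    # contrast reflected back.
    reflected = reg.positivized and x_c < 0
    if reflected:
        y_c = -reg.predict(-x_c)
        lo, hi = reg.prediction_interval(-x_c, alpha=alpha, kind=interval)
        lo, hi = -hi, -lo
    else:
        y_c = reg.predict(x_c)
        lo, hi = reg.prediction_interval(x_c, alpha=alpha, kind=interval)

    log10_gs = y_sis + y_c * den
    ival = tuple(sorted((10 ** (y_sis + lo * den), 10 ** (y_sis + hi * den))))
    # report the contrast pair on the regression's sign convention
    return GroupSizePrediction(
        x_contrast=-x_c if reflected else x_c,
        y_contrast=-y_c if reflected else y_c,
        log10_group_size=log10_gs,
        group_size=10**log10_gs,
        interval=ival,
        interval_kind=interval,
        attachment="",
        sister_value=y_sis,
        denominator=den,
    )


# ---------------------------------------------------------------------------
# packaged caviomorph data


def _data_text(name: str) -> str:
    return resources.files("pacavoc").joinpath("data", name).read_text()


def load_caviomorph_traits() -> pd.DataFrame:
    """Species trait table: mid-range group size and adult vocal repertoire size.

    Repertoire sizes count adult vocal types only (mechanical signals such
    as tooth chattering and juvenile-only calls excluded). The focal
    species carries a repertoire size but no group size: predicting the
    latter is the point of the analysis.
    """
    from io import StringIO

    df = pd.read_csv(StringIO(_data_text("caviomorph_traits.csv")))
    return df


def load_caviomorph_tree(
    include_focal: bool = True, attachment: str = "dasyprocta_cherry"
) -> Phylogeny:
    """The caviomorph topology used by the comparative analysis.

    Octodontoids ((Ctenomys talarum, Spalacopus cyanus), Octodon degus)
    versus cavioids ((Cavia aperea, (Kerodon rupestris, Hydrochoerus
    hydrochaeris)), Dasyprocta leporina), with the focal species attached
    per ``attachment`` (see :data:`ATTACHMENTS`). Topology only; apply
    :func:`nee_branch_lengths` before computing contrasts.
    """
    base = Phylogeny.from_newick(_data_text("caviomorph_tree.nwk"))
    if not include_focal:
        return base
    return attach_focal(base, FOCAL_SPECIES, attachment)


def attach_focal(tree: Phylogeny, focal: str, attachment: str) -> Phylogeny:
    """Attach the focal species to a 7-species tree at a documented position."""
    out = tree.copy()
    if attachment == "dasyprocta_cherry":
        target = out.find_tip("Dasyprocta_leporina")
        parent = out.parent_of(target)
        idx = parent.children.index(target)
        parent.children[idx] = Node(children=[target, Node(focal)])
    elif attachment == "cavioid_base":
        # sister to the whole cavioid clade
        root = out.root
        cavioid = next(
            c for c in root.children if "Dasyprocta_leporina" in c.tip_labels()
        )
        idx = root.children.index(cavioid)
        root.children[idx] = Node(children=[cavioid, Node(focal)])
    elif attachment == "root":
        out = Phylogeny(Node(children=[out.root, Node(focal)]))
        return out
    else:
        raise ValueError(f"unknown attachment {attachment!r}; options: {ATTACHMENTS}")
    return Phylogeny(out.root)


def scan_configurations(
    traits: pd.DataFrame | None = None,
    focal: str = FOCAL_SPECIES,
    reference: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Fit the comparative analysis under every documented configuration.

    The configuration space is the cross of the contrast sign convention
    (positivized vs raw child-order signs) and the focal species'
    attachment point. Returns one row per configuration with the regression
    statistics and the focal prediction; if ``reference`` supplies target
    values (keys among slope/intercept/r_squared/f_statistic/x_contrast/
    group_size), a relative-distance column ranks the configurations.
    """
    if traits is None:
        traits = load_caviomorph_traits()
    known = traits.dropna(subset=["group_size_mid"])
    rep = {r.species: math.log10(r.repertoire_size) for r in traits.itertuples()}
    gs = {r.species: math.log10(r.group_size_mid) for r in known.itertuples()}

    base = nee_branch_lengths(load_caviomorph_tree(include_focal=False))
    rows = []
    for positivize in (True, False):
        cx = pic(base, rep)
        cy = pic(base, gs)
        reg = fit_contrast_regression(cx, cy, positivize=positivize)
        for attachment in ATTACHMENTS:
            full = nee_branch_lengths(
                attach_focal(load_caviomorph_tree(include_focal=False), focal, attachment)
            )
            pred = predict_group_size(reg, full, rep, gs, focal=focal)
            rows.append(
                {
                    "sign_convention": "positivized" if positivize else "raw",
                    "attachment": attachment,
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "f_statistic": reg.f_statistic,
                    "x_contrast": pred.x_contrast,
                    "y_contrast": pred.y_contrast,
                    "log10_group_size": pred.log10_group_size,
                    "group_size": pred.group_size,
                    "interval_low": pred.interval[0],
                    "interval_high": pred.interval[1],
                }
            )
    out = pd.DataFrame(rows)
    if reference:
        dist = np.zeros(len(out))
        for key, val in reference.items():
            dist += np.abs(out[key].to_numpy() - val) / max(abs(val), 1e-12)
        out["reference_distance"] = dist
        out = out.sort_values("reference_distance").reset_index(drop=True)
    return out
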