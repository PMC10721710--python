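"""Gradient-structured synthetic community data with planted associations.

The generator emulates the data shapes of a successional-gradient field
study: ~135 plots ordered along a gradient, zero-inflated
negative-binomial counts for microbial taxa (bacteria, fungi),
logit-normal percent cover for plants, and smooth monotone measurements
for the environment.  Pairwise links of known class (positive, negative,
dome-shaped, sinusoidal, or none) are planted between chosen variables
so every pipeline stage can be validated against ground truth.

Construction: each variable has a latent Gaussian signal — a response
curve of the gradient plus, for link targets, a link function of the
source's abundance percentile plus noise — and the observed values are
obtained by a rank-preserving quantile map onto the variable's marginal
(ZINB, logit-normal, or affine).  The dependence structure of the latent
therefore passes through to the observations up to discretization,
which is exactly what a rank-based screen sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .containers import AbundanceTable, GroundTruth

LINK_CLASSES = ("positive", "negative", "dome", "sinusoid", "none")
RESPONSES = ("increasing", "decreasing", "optimum", "flat")

#: seed of the deterministic small fixture
_FIXTURE_SEED = 40412


@dataclass(frozen=True)
class VariableSpec:
    """One generated variable: response to the gradient plus marginal model."""

    name: str
    group: str
    kind: str                       # count | cover | measurement
    response: str = "flat"
    response_strength: float = 1.0
    optimum_center: float = 0.5
    optimum_width: float = 0.15
    latent_noise_sd: float = 1.0
    # count marginal (zero-inflated negative binomial)
    nb_mean: float = 50.0
    nb_dispersion: float = 0.5
    zero_inflation: float = 0.3
    # cover marginal (logit-normal percent)
    cover_logit_mean: float = -2.0
    cover_logit_sd: float = 1.0
    # measurement marginal (affine latent)
    meas_loc: float = 0.0
    meas_scale: float = 1.0


@dataclass(frozen=True)
class LinkSpec:
    """One planted directed link source -> target of a known class."""

    source: str
    target: str
    klass: str
    effect: float = 1.0
    noise_sd: float = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset (same seed -> same data)."""

    n_plots: int = 135
    variables: tuple[VariableSpec, ...] = ()
    links: tuple[LinkSpec, ...] = ()
    seed: int = 0


def _response_curve(spec: VariableSpec, g: np.ndarray) -> np.ndarray:
    if spec.response == "increasing":
        return g - 0.5
    if spec.response == "decreasing":
        return 0.5 - g
    if spec.response == "optimum":
        return np.exp(-0.5 * ((g - spec.optimum_center) / spec.optimum_width) ** 2)
    if spec.response == "flat":
        return np.zeros_like(g)
    raise ValueError(f"unknown response type: {spec.response!r}")


def _link_function(klass: str, u: np.ndarray) -> np.ndarray:
    if klass == "positive":
        return u
    if klass == "negative":
        return -u
    if klass == "dome":
        # symmetric quadratic with interior optimum at u = 0.5 => expected m ~ 0
        return 1.0 - 4.0 * (u - 0.5) ** 2
    if klass == "sinusoid":
        # 1.5 periods over the source's range: an integer period count has
        # Spearman rho = -0.75/k against u, whereas 1.5 periods gives rho ~ 0
        return np.sin(3.0 * np.pi * u)
    if klass == "none":
        return np.zeros_like(u)
    raise ValueError(f"unknown link class: {klass!r}")


def _present_percentile(values: np.ndarray, kind: str) -> np.ndarray:
    """Percentile of each plot's value among plots where the variable is
    present; 0.5 (neutral) where it is absent.  Matches the screening's
    co-occurrence conditioning, so a planted dome stays symmetric on the
    plots that actually enter the pair's estimate."""
    present = values > 0 if kind in ("count", "cover") else np.ones_like(values, bool)
    u = np.full(values.shape, 0.5)
    if present.sum() >= 2:
        r = stats.rankdata(values[present])
        u[present] = (r - 0.5) / present.sum()
    return u


def _marginalize(spec: VariableSpec, latent: np.ndarray,
                 g: np.ndarray) -> np.ndarray:
    n = latent.size
    if spec.kind == "measurement":
        return spec.meas_loc + spec.meas_scale * latent
    u = (stats.rankdata(latent) - 0.5) / n
    if spec.kind == "cover":
        return 100.0 * expit(spec.cover_logit_mean
                             + spec.cover_logit_sd * stats.norm.ppf(u))
    if spec.kind == "count":
        pi = spec.zero_inflation
        k = spec.nb_dispersion
        p = k / (k + spec.nb_mean)
        u_nb = np.clip((u - pi) / (1.0 - pi), 0.0, 1.0 - 1e-12)
        counts = stats.nbinom.ppf(u_nb, k, p)
        counts[u_nb <= 0.0] = 0.0  # discrete ppf(0) is -1 by convention
        return counts
    raise ValueError(f"unknown kind: {spec.kind!r}")


def _validate(spec: SyntheticSpec) -> None:
    names = [v.name for v in spec.variables]
    if len(set(names)) != len(names):
        raise ValueError("duplicated variable names in spec")
    targets = set()
    for link in spec.links:
        if link.source not in names or link.target not in names:
            raise ValueError(f"link references unknown variable: {link}")
        if link.klass not in LINK_CLASSES:
            raise ValueError(f"unknown link class: {link.klass!r}")
        if link.effect <= 0:
            raise ValueError("link effect sizes must be > 0")
        if link.target in targets:
            raise ValueError(f"variable {link.target!r} is target of two links")
        targets.add(link.target)
    for link in spec.links:
        if link.source in targets:
            raise ValueError(
                f"link source {link.source!r} is itself a link target "
                "(chained links are not supported)")


def generate(spec: SyntheticSpec) -> tuple[AbundanceTable, GroundTruth]:
    """Generate one dataset and its ground truth from a SyntheticSpec."""
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_plots
    g = np.linspace(0.0, 1.0, n)
    plots = [f"plot{i + 1:03d}" for i in range(n)]
    link_for = {l.target: l for l in spec.links}
    values: dict[str, np.ndarray] = {}

    # link sources (and unlinked variables) first, targets second
    ordered = ([v for v in spec.variables if v.name not in link_for]
               + [v for v in spec.variables if v.name in link_for])
    # noise drawn in spec order so the stream is independent of topology
    noise = {v.name: rng.normal(0.0, 1.0, n) for v in spec.variables}
    for v in ordered:
        latent = v.response_strength * _response_curve(v, g)
        link = link_for.get(v.name)
        if link is not None:
            src = next(s for s in spec.variables if s.name == link.source)
            u_src = _present_percentile(values[link.source], src.kind)
            latent = latent + link.effect * _link_function(link.klass, u_src)
            latent = latent + link.noise_sd * noise[v.name]
        else:
            latent = latent + v.latent_noise_sd * noise[v.name]
        values[v.name] = _marginalize(v, latent, g)

    frame = pd.DataFrame({v.name: values[v.name] for v in spec.variables},
                         index=pd.Index(plots, name="plot"))
    tbl = AbundanceTable(
        values=frame,
        groups=pd.Series({v.name: v.group for v in spec.variables}),
        gradient=pd.Series(g, index=frame.index),
        kind=pd.Series({v.name: v.kind for v in spec.variables}),
    )
    truth = GroundTruth(
        links=pd.DataFrame(
            [{"source": l.source, "target": l.target, "klass": l.klass,
              "effect": l.effect, "noise_sd": l.noise_sd} for l in spec.links],
            columns=["source", "target", "klass", "effect", "noise_sd"]),
        variables=pd.DataFrame(
            [{"variable": v.name, "group": v.group, "kind": v.kind,
              "response": v.response} for v in spec.variables]),
    )
    return tbl, truth


def independent_spec(n_plots: int = 135, n_vars: int = 40, seed: int = 0,
                     kind: str = "measurement",
                     groups: tuple[str, str] = ("Bacteria", "Fungi")) -> SyntheticSpec:
    """All-independent dataset (no gradient response, no links): the null
    condition for calibration and coupling-centering checks.  Variables
    alternate between two constituent groups."""
    variables = tuple(
        VariableSpec(name=f"v{i + 1:03d}", group=groups[i % 2], kind=kind,
                     response="flat")
        for i in range(n_vars)
    )
    return SyntheticSpec(n_plots=n_plots, variables=variables, links=(), seed=seed)


def planted_links_spec(n_plots: int = 135, seed: int = 0,
                       effect: float = 1.0, noise_sd: float = 0.1) -> SyntheticSpec:
    """One planted link of each class from a microbial count source (ZINB,
    dispersion 0.5, 30% zero inflation) onto a plant percent-cover target.

    Used by the classifier-recovery experiments.  Targets are zero-free
    cover variables so the co-occurrence subset is exactly the plots where
    the source is present — the plots on which the planted function is
    expressed over its full range.  (A zero-inflated target censors its
    own low-abundance arm, which truncates dome and sinusoid shapes: a
    detectability limit of presence-conditioned screens, not a property
    of the classifier this experiment measures.)
    """
    variables = []
    links = []
    for tag, klass in (("pos", "positive"), ("neg", "negative"),
                       ("dome", "dome"), ("sin", "sinusoid"),
                       ("none", "none")):
        variables.append(VariableSpec(f"src_{tag}", "Fungi", "count", response="flat"))
        variables.append(VariableSpec(f"tgt_{tag}", "Plants", "cover", response="flat"))
        links.append(LinkSpec(f"src_{tag}", f"tgt_{tag}", klass,
                              effect=effect, noise_sd=noise_sd))
    return SyntheticSpec(n_plots=n_plots, variables=tuple(variables),
                         links=tuple(links), seed=seed)


def fixture_spec(seed: int = _FIXTURE_SEED) -> SyntheticSpec:
    """Spec of the deterministic 40-plot, 12-variable fixture."""
    # milder overdispersion than the study-scale default: with only six
    # count variables per plot the CSS scaling factor is itself noisy, and
    # extreme dispersion would let that noise swamp the planted links
    count_kw = dict(kind="count", zero_inflation=0.2, nb_mean=100.0,
                    nb_dispersion=2.0)
    variables = (
        VariableSpec("env_temp", "Environment", "measurement",
                     response="decreasing", response_strength=3.0,
                     latent_noise_sd=0.3, meas_loc=8.0, meas_scale=1.5),
        VariableSpec("env_ph", "Environment", "measurement",
                     response="decreasing", response_strength=3.0,
                     latent_noise_sd=0.3, meas_loc=6.5, meas_scale=0.4),
        VariableSpec("env_nitrogen", "Environment", "measurement",
                     response="increasing", response_strength=3.0,
                     latent_noise_sd=0.3, meas_loc=2.0, meas_scale=0.8),
        VariableSpec("plant_pioneer", "Plants", "cover",
                     response="decreasing", response_strength=2.0),
        VariableSpec("plant_dome", "Plants", "cover", response="flat"),
        VariableSpec("plant_late", "Plants", "cover",
                     response="optimum", optimum_center=0.8, response_strength=2.0),
        VariableSpec("fungus_a", "Fungi", response="flat", **count_kw),
        VariableSpec("fungus_b", "Fungi", response="flat", **count_kw),
        VariableSpec("fungus_c", "Fungi", response="flat", **count_kw),
        VariableSpec("bact_a", "Bacteria", response="flat", **count_kw),
        VariableSpec("bact_b", "Bacteria", response="flat", **count_kw),
        VariableSpec("bact_c", "Bacteria", response="flat", **count_kw),
    )
    links = (
        LinkSpec("fungus_a", "bact_a", "positive"),
        LinkSpec("plant_pioneer", "fungus_b", "negative"),
        LinkSpec("env_temp", "plant_dome", "dome"),
        LinkSpec("env_nitrogen", "bact_b", "sinusoid"),
        LinkSpec("fungus_c", "bact_c", "none"),
    )
    return SyntheticSpec(n_plots=40, variables=variables, links=links, seed=seed)


def spec_from_dict(data: dict) -> SyntheticSpec:
    """Build a SyntheticSpec from a plain dict (e.g. parsed YAML).

    Expected keys: n_plots, seed, variables (list of VariableSpec field
    dicts), links (list of LinkSpec field dicts).
    """
    variables = tuple(VariableSpec(**v) for v in data.get("variables", []))
    links = tuple(LinkSpec(**l) for l in data.get("links", []))
    return SyntheticSpec(n_plots=int(data.get("n_plots", 135)),
                         variables=variables, links=links,
                         seed=int(data.get("seed", 0)))


def fixture_small() -> tuple[AbundanceTable, GroundTruth]:
    """Deterministic 40-plot, 12-variable dataset with one planted link of
    each class; regenerated from a frozen spec for fast tests and docs."""
    return generate(fixture_spec())
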