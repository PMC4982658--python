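"""Stochastic simulator of adhesion-site assembly.

Each simulated adhesion offers a number of binding sites ``N`` drawn from a
configurable distribution; recruited proteins occupy sites as realizations
of a binomial process with binding probability ``p``.  Two effective knobs
reproduce the sources of compositional variation:

* **diversity** — widening the distribution of ``N`` (local cues and
  maturation differ between adhesions, scaling all components together);
* **noise** — widening the distribution from which ``p`` is drawn per
  adhesion (stochastic realization of alternative binding options).

Supported topologies:

``noncompetitive``
    Each protein binds its own (possibly stoichiometry-scaled) pool of
    sites: counts are independent binomials given ``N``.
``competitive``
    All proteins compete for the same ``N`` sites; occupancies are a single
    multinomial draw, so one site hosts at most one protein.
``multistep``
    Ordered recruitment layers: the count of a layer-k protein serves as the
    site count for the layer-(k+1) proteins it recruits.  Noise accumulates
    along the steps.

The total level ``P^T`` of a protein is the sum of its counts over all
layers/assemblies of an adhesion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import noise_infer
from .noise_infer import Verdict, infer_change
from .tables import DensityTable

TOPOLOGIES = ("competitive", "noncompetitive", "multistep")
SITE_FAMILIES = ("uniform", "normal", "poisson")


class ParameterError(ValueError):
    """Invalid simulator parameterization."""


# ---------------------------------------------------------------------------
# model description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteDistribution:
    """Distribution of the per-adhesion binding-site count ``N``.

    ``uniform``: integers in ``mean ± width/2``; ``normal``: sd ``width/4``,
    truncated at 0; ``poisson``: parameterized by ``mean`` (width ignored).
    Drawn values are rounded to the nearest nonnegative integer.
    """

    family: str = "uniform"
    mean: float = 1000.0
    width: float = 0.0

    def validate(self) -> None:
        if self.family not in SITE_FAMILIES:
            raise ParameterError(f"unknown site distribution family {self.family!r}")
        if self.mean < 0 or self.width < 0:
            raise ParameterError("site distribution mean and width must be >= 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        self.validate()
        if self.family == "uniform":
            vals = rng.uniform(self.mean - self.width / 2, self.mean + self.width / 2, n)
        elif self.family == "normal":
            vals = rng.normal(self.mean, self.width / 4 if self.width > 0 else 0.0, n)
        else:  # poisson
            return rng.poisson(self.mean, n).astype(np.int64)
        return np.maximum(np.rint(vals), 0).astype(np.int64)


@dataclass(frozen=True)
class BindingSpec:
    """Binding parameters of one recruited protein.

    ``p_mean`` is the center of the binding probability; ``noise_width`` the
    width of the uniform distribution from which ``p`` is drawn once per
    adhesion (clamped to [0, 1]); ``stoichiometry`` scales the number of
    sites offered to this protein (noncompetitive unequal-sites variant);
    ``parent`` names the recruiting protein for multistep layers > 1.
    """

    p_mean: float
    noise_width: float = 0.0
    stoichiometry: float = 1.0
    parent: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.p_mean < 1.0:
            raise ParameterError(f"p_mean must be in (0,1), got {self.p_mean}")
        if self.noise_width < 0:
            raise ParameterError("noise_width must be >= 0")
        if self.stoichiometry <= 0:
            raise ParameterError("stoichiometry must be > 0")

    def draw_p(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = self.noise_width
        if w == 0:
            return np.full(n, self.p_mean)
        return np.clip(rng.uniform(self.p_mean - w / 2, self.p_mean + w / 2, n), 0.0, 1.0)


@dataclass(frozen=True)
class AssemblyModel:
    """Topology plus distributions parameterizing the recruitment simulator."""

    topology: str
    sites: SiteDistribution
    layers: tuple[Mapping[str, BindingSpec], ...]

    def validate(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ParameterError(f"unknown topology {self.topology!r}")
        self.sites.validate()
        if not self.layers or not self.layers[0]:
            raise ParameterError("at least one recruitment layer with one protein")
        names_seen: set[str] = set()
        for k, layer in enumerate(self.layers):
            for name, spec in layer.items():
                spec.validate()
                if k == 0 and spec.parent is not None:
                    raise ParameterError(f"layer-1 protein {name!r} cannot have a parent")
                if k > 0:
                    if spec.parent is None:
                        raise ParameterError(f"layer-{k + 1} protein {name!r} needs a parent")
                    if spec.parent not in self.layers[k - 1]:
                        raise ParameterError(
                            f"parent {spec.parent!r} of {name!r} not in layer {k}"
                        )
            names_seen |= set(layer)
        if self.topology != "multistep" and len(self.layers) != 1:
            raise ParameterError(f"{self.topology} topology takes exactly one layer")
        if self.topology == "competitive":
            total = sum(s.p_mean for s in self.layers[0].values())
            if total > 1.0 + 1e-12:
                raise ParameterError(
                    f"competitive binding probabilities must sum to <= 1, got {total:.3f}"
                )

    @property
    def proteins(self) -> tuple[str, ...]:
        out: list[str] = []
        for layer in self.layers:
            out.extend(p for p in layer if p not in out)
        return tuple(out)

    # -- constructors --------------------------------------------------------

    @classmethod
    def noncompetitive(
        cls, proteins: Mapping[str, BindingSpec], sites: SiteDistribution
    ) -> "AssemblyModel":
        return cls("noncompetitive", sites, (dict(proteins),))

    @classmethod
    def competitive(
        cls, proteins: Mapping[str, BindingSpec], sites: SiteDistribution
    ) -> "AssemblyModel":
        return cls("competitive", sites, (dict(proteins),))

    @classmethod
    def multistep(
        cls, layers: Sequence[Mapping[str, BindingSpec]], sites: SiteDistribution
    ) -> "AssemblyModel":
        return cls("multistep", sites, tuple(dict(l) for l in layers))

    def with_levels(
        self, noise_width: float | None = None, diversity_width: float | None = None
    ) -> "AssemblyModel":
        """A copy with every protein's noise width and/or the site-count
        distribution width replaced — the two axes of the validation grids."""
        sites = self.sites if diversity_width is None else replace(self.sites, width=diversity_width)
        if noise_width is None:
            layers = self.layers
        else:
            layers = tuple(
                {n: replace(s, noise_width=noise_width) for n, s in layer.items()}
                for layer in self.layers
            )
        return AssemblyModel(self.topology, sites, layers)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Simulated per-adhesion protein counts with full ground truth.

    ``layer_counts[k][protein]`` is the per-adhesion count of ``protein``
    recruited in layer ``k``; ``truth`` stores the drawn ``N`` and per-layer
    ``p`` arrays.  Densities are reproducible bit-for-bit from
    ``(model, n, seed)``.
    """

    model: AssemblyModel
    n_adhesions: int
    seed: int
    layer_counts: list[dict[str, np.ndarray]]
    truth: dict

    @property
    def proteins(self) -> tuple[str, ...]:
        return self.model.proteins


def simulate_adhesion_set(
    model: AssemblyModel, n_adhesions: int, seed: int
) -> SimulatedDataset:
    """Simulate ``n_adhesions`` adhesions under ``model``.

    Per adhesion: a site count ``N`` is drawn from the model's site
    distribution, each protein's ``p`` is drawn once from its noise
    distribution, and occupancies are realized binomially (independently
    for noncompetitive layers, jointly multinomially for competitive).
    """
    model.validate()
    if n_adhesions < 1:
        raise ParameterError("n_adhesions must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_adhesions
    N = model.sites.draw(rng, n)
    truth: dict = {"N": N, "p": []}
    layer_counts: list[dict[str, np.ndarray]] = []

    if model.topology == "competitive":
        layer = model.layers[0]
        names = list(layer)
        P = np.column_stack([layer[m].draw_p(rng, n) for m in names])
        # renormalize rare noise draws whose probabilities sum past 1
        totals = P.sum(axis=1)
        over = totals > 1.0
        if over.any():
            P[over] /= totals[over, None]
        pvals = np.column_stack([P, 1.0 - P.sum(axis=1)])
        pvals = np.clip(pvals, 0.0, None)
        pvals /= pvals.sum(axis=1, keepdims=True)
        occ = np.empty((n, len(names)), dtype=np.int64)
        counts = rng.multinomial(N, pvals)  # broadcast over rows
        occ[:] = counts[..., : len(names)]
        layer_counts.append({m: occ[:, j].copy() for j, m in enumerate(names)})
        truth["p"].append({m: P[:, j].copy() for j, m in enumerate(names)})
    else:
        parent_counts: dict[str, np.ndarray] = {}
        for k, layer in enumerate(model.layers):
            counts_k: dict[str, np.ndarray] = {}
            p_k: dict[str, np.ndarray] = {}
            for name, spec in layer.items():
                base = N if k == 0 else parent_counts[spec.parent]
                sites = np.maximum(np.rint(base * spec.stoichiometry), 0).astype(np.int64)
                p = spec.draw_p(rng, n)
                counts_k[name] = rng.binomial(sites, p)
                p_k[name] = p
            layer_counts.append(counts_k)
            truth["p"].append(p_k)
            parent_counts = counts_k

    return SimulatedDataset(
        model=model, n_adhesions=n, seed=seed, layer_counts=layer_counts, truth=truth
    )


def total_levels(dataset: SimulatedDataset, dataset_id: str = "SIM") -> DensityTable:
    """Total level ``P^T`` per protein: the sum of its counts over all layers
    of each adhesion, as a :class:`DensityTable`."""
    proteins = dataset.proteins
    totals = {p: np.zeros(dataset.n_adhesions, dtype=float) for p in proteins}
    for layer in dataset.layer_counts:
        for name, counts in layer.items():
            totals[name] += counts
    data = pd.DataFrame(totals, columns=list(proteins))
    data.insert(0, "adhesion_id", np.arange(dataset.n_adhesions))
    return DensityTable(data=data, components=proteins, dataset_id=dataset_id)


def layer_totals(dataset: SimulatedDataset, layer: int) -> pd.DataFrame:
    """Per-adhesion counts of the proteins recruited in one layer."""
    return pd.DataFrame(dataset.layer_counts[layer])


# ---------------------------------------------------------------------------
# validation of the inference rules on the simulator
# ---------------------------------------------------------------------------

def consistent_verdicts(d_noise: float, d_diversity: float) -> frozenset[Verdict]:
    """Verdicts consistent with an imposed (noise, diversity) change.

    The expected-region logic: a pure noise increase must read
    ``noise_lower_in_1``; a pure diversity increase ``diversity_higher_in_2``;
    when both change, any verdict whose unambiguous sign component matches
    is admissible (e.g. noise and diversity both up guarantee CV up but
    leave the sign of Δr² open).
    """
    sn, sd = np.sign(d_noise), np.sign(d_diversity)
    if sn == 0 and sd == 0:
        return frozenset({Verdict.INCONCLUSIVE})
    table = {
        (1, 0): {Verdict.NOISE_LOWER_IN_1},
        (-1, 0): {Verdict.NOISE_LOWER_IN_2},
        (0, 1): {Verdict.DIVERSITY_HIGHER_IN_2},
        (0, -1): {Verdict.DIVERSITY_HIGHER_IN_1},
        (1, 1): {Verdict.NOISE_LOWER_IN_1, Verdict.DIVERSITY_HIGHER_IN_2},
        (1, -1): {Verdict.NOISE_LOWER_IN_1, Verdict.DIVERSITY_HIGHER_IN_1},
        (-1, 1): {Verdict.NOISE_LOWER_IN_2, Verdict.DIVERSITY_HIGHER_IN_2},
        (-1, -1): {Verdict.NOISE_LOWER_IN_2, Verdict.DIVERSITY_HIGHER_IN_1},
    }
    return frozenset(table[(int(sn), int(sd))])


def compare_simulated(
    model1: AssemblyModel,
    model2: AssemblyModel,
    n_adhesions: int,
    seed: int,
) -> tuple[Verdict, noise_infer.DeltaMeasure, noise_infer.DeltaMeasure]:
    """Simulate one dataset per model and run the Δlog CV / Δr² inference
    on the total levels (category 1 = model1, category 2 = model2)."""
    t1 = total_levels(simulate_adhesion_set(model1, n_adhesions, seed))
    t2 = total_levels(simulate_adhesion_set(model2, n_adhesions, seed + 1))
    dcv = noise_infer.delta_log_cv([t1], [t2])
    dr2 = noise_infer.delta_r2([t1], [t2], use_zscores=False)
    return infer_change(dcv, dr2), dcv, dr2


def inference_validation_grid(
    model_template: AssemblyModel,
    noise_levels: Sequence[float],
    diversity_levels: Sequence[float],
    n_adhesions: int = 2000,
    reps: int = 20,
    seed: int = 0,
    include_self_pairs: bool = False,
) -> pd.DataFrame:
    """Systematic screen of the inference rules over a noise x diversity grid.

    For every ordered pair of grid cells, ``reps`` replicate comparisons are
    simulated and the fraction of verdicts consistent with the imposed
    change (per :func:`consistent_verdicts`) is tabulated.

    Returns a DataFrame with one row per ordered cell pair:
    ``noise1, diversity1, noise2, diversity2, n_reps, frac_consistent`` plus
    one ``frac_<verdict>`` column per verdict value.
    """
    if len(noise_levels) < 2 and len(diversity_levels) < 2 and not include_self_pairs:
        raise ParameterError("need at least 2 levels on one axis")
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    cells = [(w, d) for w in noise_levels for d in diversity_levels]
    rng = np.random.default_rng(seed)
    rows = []
    for w1, d1 in cells:
        for w2, d2 in cells:
            if (w1, d1) == (w2, d2) and not include_self_pairs:
                continue
            expected = consistent_verdicts(w2 - w1, d2 - d1)
            m1 = model_template.with_levels(noise_width=w1, diversity_width=d1)
            m2 = model_template.with_levels(noise_width=w2, diversity_width=d2)
            tallies = {v: 0 for v in Verdict}
            hits = 0
            for _ in range(reps):
                s = int(rng.integers(0, 2**31 - 2))
                verdict, _, _ = compare_simulated(m1, m2, n_adhesions, s)
                tallies[verdict] += 1
                hits += verdict in expected
            row = {
                "noise1": w1, "diversity1": d1, "noise2": w2, "diversity2": d2,
                "n_reps": reps, "frac_consistent": hits / reps,
            }
            row.update({f"frac_{v.value}": tallies[v] / reps for v in Verdict})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# declarative model configs and dataset persistence
# ---------------------------------------------------------------------------

def model_from_dict(raw: Mapping) -> AssemblyModel:
    """Build an AssemblyModel from a declarative mapping.

    Schema::

        topology: competitive | noncompetitive | multistep
        sites: {family, mean, width}
        layers:                      # or a single "proteins" mapping
          - proteinA: {p_mean, noise_width, stoichiometry}
          - proteinB: {p_mean, ..., parent: proteinA}
    """
    raw = dict(raw)
    try:
        topology = raw["topology"]
        sites = SiteDistribution(**raw.get("sites", {}))
        if "layers" in raw:
            layers = tuple(
                {name: BindingSpec(**spec) for name, spec in layer.items()}
                for layer in raw["layers"]
            )
        else:
            layers = ({name: BindingSpec(**spec) for name, spec in raw["proteins"].items()},)
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"invalid model config: {exc}") from exc
    model = AssemblyModel(topology, sites, layers)
    model.validate()
    return model


def model_from_file(path) -> AssemblyModel:
    """Read a model config from JSON or YAML."""
    import json
    from pathlib import Path

    import yaml

    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    return model_from_dict(raw)


def save_simulated(dataset: SimulatedDataset, path) -> None:
    """Write total levels as CSV with a JSON sidecar of truth parameters."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    total_levels(dataset).to_csv(path)
    truth = {
        "seed": dataset.seed,
        "n_adhesions": dataset.n_adhesions,
        "model": {
            "topology": dataset.model.topology,
            "sites": dataclasses.asdict(dataset.model.sites),
            "layers": [
                {name: dataclasses.asdict(spec) for name, spec in layer.items()}
                for layer in dataset.model.layers
            ],
        },
        "N_mean": float(np.mean(dataset.truth["N"])),
        "p_mean_per_layer": [
            {name: float(np.mean(p)) for name, p in layer.items()}
            for layer in dataset.truth["p"]
        ],
    }
    path.with_name(path.stem + "_truth.json").write_text(json.dumps(truth, indent=2))
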