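"""Synthetic inputs with planted, self-validating structure.

Everything downstream modules consume can be generated here: expression
datasets with planted differential expression (a mean shift of +/-delta on
Gaussian log-scale noise around a baseline), signature stores with one
planted query-correlated signature among random decoys, and toy interaction
tables, alias dictionaries, annotations, citations and stoplists.  All
generators are deterministic per seed and record their parameters in truth
manifests so tests can validate recovery against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    SignatureStore,
    write_annotations,
    write_citations,
    write_expression_matrix,
    write_gene_list,
    write_gmt_query,
    write_sample_meta,
)
from .matching import QueryGeneSet
from .signatures import DataError, ExpressionDataset, Publication, RankedSignature

_AUTHOR_POOL = (
    "Smith, Jane", "Garcia, Luis", "Okoye, Amara", "Chen, Wei",
    "Nakamura, Yuki", "Muller, Hans", "Silva, Ana", "Kowalski, Piotr",
)
_DRUG_VOCAB = (
    "trichostatin a", "vorinostat", "resveratrol", "tanespimycin",
    "sirolimus", "metformin", "trifluoperazine", "imatinib",
)
_DISEASE_VOCAB = (
    "glioblastoma", "gastric cancer", "neurofibromatosis", "melanoma",
    "breast cancer", "schwannoma",
)
_STOP_TERMS = ("cells", "tissue", "sample", "expression", "treatment")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a planted two-class differential-expression dataset.

    ``n_de`` genes are shifted in the test class: the first half up by
    ``delta`` log-units, the second half down.  ``sigma`` is the noise SD
    (Student-t noise with ``df`` degrees of freedom when ``heavy_tail``).
    """

    n_genes: int = 200
    n_per_class: int = 3
    n_de: int = 20
    delta: float = 3.0
    sigma: float = 1.0
    baseline: float = 8.0
    seed: int = 0
    heavy_tail: bool = False
    df: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_de <= self.n_genes:
            raise DataError("need 0 <= n_de <= n_genes")
        if self.sigma <= 0:
            raise DataError("noise sigma must be positive")
        if self.n_per_class < 1 or self.n_genes < 2:
            raise DataError("need >=1 sample per class and >=2 genes")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def planted_up(self) -> list[str]:
        return self.gene_names()[: self.n_de - self.n_de // 2]

    def planted_down(self) -> list[str]:
        return self.gene_names()[self.n_de - self.n_de // 2 : self.n_de]


def simulate_expression(
    spec: SimSpec, dataset_id: str = "SIM1"
) -> ExpressionDataset:
    """Two-class dataset ('control' vs 'treated') with planted DE genes."""
    rng = np.random.default_rng(spec.seed)
    n_samples = 2 * spec.n_per_class
    if spec.heavy_tail:
        scale = spec.sigma / np.sqrt(spec.df / (spec.df - 2))
        noise = scale * rng.standard_t(spec.df, size=(spec.n_genes, n_samples))
    else:
        noise = rng.normal(0.0, spec.sigma, size=(spec.n_genes, n_samples))
    values = spec.baseline + noise
    n_up = spec.n_de - spec.n_de // 2
    values[:n_up, spec.n_per_class:] += spec.delta
    values[n_up:spec.n_de, spec.n_per_class:] -= spec.delta
    samples = [f"ctl_{i + 1}" for i in range(spec.n_per_class)] + [
        f"trt_{i + 1}" for i in range(spec.n_per_class)
    ]
    matrix = pd.DataFrame(values, index=spec.gene_names(), columns=samples)
    matrix.index.name = "gene"
    meta = pd.DataFrame(
        {"agent": ["control"] * spec.n_per_class + ["treated"] * spec.n_per_class},
        index=pd.Index(samples, name="sample"),
    )
    citations = [
        Publication(
            title=f"Synthetic study {dataset_id}",
            authors=_AUTHOR_POOL[:3],
        )
    ]
    return ExpressionDataset(
        dataset_id=dataset_id, matrix=matrix, sample_meta=meta,
        citations=citations,
    )


@dataclass(frozen=True)
class StoreSpec:
    """Parameters of a synthetic signature store with one planted signature.

    ``rho`` is the planted concordance: each query up-gene lands in the top
    block (down-gene in the bottom block) of the planted signature with
    probability |rho|, at a random interior position otherwise; negative
    ``rho`` plants an anti-match (blocks swapped).  Decoys are the same
    universe in random order.
    """

    n_decoys: int = 200
    n_genes: int = 500
    rho: float = 1.0
    seed: int = 0
    tagged: bool = True

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise DataError("rho must lie in [-1, 1]")
        if self.n_decoys < 0 or self.n_genes < 4:
            raise DataError("need n_decoys >= 0 and n_genes >= 4")


def _signature(sig_id: str, genes: np.ndarray, rng: np.random.Generator) -> RankedSignature:
    stats = np.sort(rng.normal(0.0, 2.0, size=len(genes)))[::-1]
    return RankedSignature(
        signature_id=sig_id, genes=tuple(genes), stats=stats,
        stat_kind="t", direction_known=True,
    )


def make_synthetic_store(
    query: QueryGeneSet, spec: StoreSpec
) -> tuple[SignatureStore, dict]:
    """Signature store of random decoys plus one query-correlated plant.

    Returns the store and a truth manifest recording the planted signature
    id and the generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    query_genes = sorted(query.up | query.down)
    if len(query_genes) >= spec.n_genes:
        raise DataError(
            f"query has {len(query_genes)} genes but universe holds only "
            f"{spec.n_genes}"
        )
    width = len(str(spec.n_genes + len(query_genes)))
    universe = list(query_genes)
    i = 0
    while len(universe) < spec.n_genes:
        name = f"SG{i + 1:0{width}d}"
        i += 1
        if name not in query.up and name not in query.down:
            universe.append(name)
    universe = np.array(sorted(universe))

    store = SignatureStore()
    for d in range(spec.n_decoys):
        ds_id = f"SIMD{d + 1:04d}"
        sig = _signature(
            f"{ds_id}:agent:treated_vs_control",
            rng.permutation(universe), rng,
        )
        tags, citations = _toy_knowledge(rng) if spec.tagged else ([], [])
        store.add(sig, ds_id, tags=tags, citations=citations)

    up = sorted(query.up)
    down = sorted(query.down)
    planted_up = [g for g in up if rng.random() < abs(spec.rho)]
    planted_down = [g for g in down if rng.random() < abs(spec.rho)]
    if spec.rho < 0:
        planted_up, planted_down = planted_down, planted_up
    middle = [g for g in universe if g not in planted_up and g not in planted_down]
    order = np.concatenate([
        rng.permutation(planted_up) if planted_up else np.empty(0, dtype=universe.dtype),
        rng.permutation(middle),
        rng.permutation(planted_down) if planted_down else np.empty(0, dtype=universe.dtype),
    ])
    planted_id = "SIMPL0001:agent:treated_vs_control"
    sig = _signature(planted_id, order, rng)
    tags, citations = _toy_knowledge(rng) if spec.tagged else ([], [])
    store.add(sig, "SIMPL0001", tags=tags, citations=citations)

    truth = {"planted_signature_id": planted_id, **asdict(spec)}
    return store, truth


def _toy_knowledge(
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str]], list[Publication]]:
    tags = []
    if rng.random() < 0.8:
        tags.append((_DRUG_VOCAB[rng.integers(len(_DRUG_VOCAB))], "drug"))
    if rng.random() < 0.6:
        tags.append((_DISEASE_VOCAB[rng.integers(len(_DISEASE_VOCAB))], "disease"))
    authors = tuple(
        _AUTHOR_POOL[j]
        for j in sorted(rng.choice(len(_AUTHOR_POOL), size=3, replace=False))
    )
    citations = [Publication(title="Synthetic source study", authors=authors)]
    return tags, citations


def keyword_tag(
    description: str,
    drug_vocab: tuple[str, ...] = _DRUG_VOCAB,
    disease_vocab: tuple[str, ...] = _DISEASE_VOCAB,
) -> list[tuple[str, str]]:
    """Plain substring tagger for fixture generation only — not NLP.

    Scans a free-text description for known drug/disease names; real
    annotation terms are expected to arrive as precomputed sidecar files.
    """
    text = description.lower()
    tags = [(term, "drug") for term in drug_vocab if term in text]
    tags += [(term, "disease") for term in disease_vocab if term in text]
    return tags


def write_demo_workspace(outdir, seed: int = 0) -> dict:
    """Emit a complete toy workspace in the layouts the CLI consumes.

    Creates an expression dataset (matrix, sample metadata, citations), a
    ready-made synthetic signature store with annotations, a planted query
    (plain lists and GMT), a toy miRNA interaction table plus alias
    dictionary, and a stoplist.  Returns the truth manifest, which is also
    written to ``truth.json``.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)

    ds_dir = outdir / "dataset"
    ds_dir.mkdir(parents=True, exist_ok=True)
    sim = SimSpec(n_genes=400, n_per_class=3, n_de=20, delta=3.0, sigma=1.0,
                  seed=int(rng.integers(2**31)))
    dataset = simulate_expression(sim, dataset_id="SIMDS01")
    write_expression_matrix(dataset.matrix, ds_dir / "matrix.tsv")
    write_sample_meta(dataset.sample_meta, ds_dir / "samples.tsv")
    write_citations(dataset.citations, ds_dir / "citations.json")

    query = QueryGeneSet.from_lists(
        up=[f"Q{i + 1:03d}U" for i in range(15)],
        down=[f"Q{i + 1:03d}D" for i in range(15)],
    )
    qdir = outdir / "query"
    qdir.mkdir(exist_ok=True)
    write_gene_list(query.up, qdir / "up.txt")
    write_gene_list(query.down, qdir / "down.txt")
    write_gmt_query(query, qdir / "query.gmt", name="demo")

    st_spec = StoreSpec(n_decoys=60, n_genes=300, rho=1.0,
                        seed=int(rng.integers(2**31)))
    store, truth = make_synthetic_store(query, st_spec)
    store.save(outdir / "store")

    mdir = outdir / "mirna"
    mdir.mkdir(exist_ok=True)
    mirnas = [f"hsa-miR-{n}-5p" for n in (21, 34, 155, 200, 7)]
    with open(mdir / "interactions.tsv", "w", encoding="utf-8", newline="\n") as fh:
        for m, mir in enumerate(mirnas):
            targets = rng.choice(300, size=6, replace=False)
            for t in sorted(targets):
                fh.write(f"{mir}\tSG{t + 1:03d}\t{int(rng.integers(1, 5))}\n")
    with open(mdir / "aliases.tsv", "w", encoding="utf-8", newline="\n") as fh:
        for mir in mirnas:
            short = mir.replace("hsa-miR-", "miR").replace("-5p", "")
            fh.write(f"{short}\t{mir}\n")
    with open(mdir / "up_mirnas.txt", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(mirnas[0] + "\n" + mirnas[1] + "\n")
    with open(mdir / "down_mirnas.txt", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(mirnas[2] + "\n")

    with open(outdir / "stoplist.txt", "w", encoding="utf-8", newline="\n") as fh:
        for term in _STOP_TERMS:
            fh.write(term + "\n")

    truth = {
        "seed": seed,
        "dataset": {**asdict(sim), "dataset_id": "SIMDS01",
                    "planted_up": sim.planted_up(),
                    "planted_down": sim.planted_down()},
        "store": truth,
    }
    (outdir / "truth.json").write_text(
        json.dumps(truth, indent=2) + "\n", encoding="utf-8"
    )
    return truth
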