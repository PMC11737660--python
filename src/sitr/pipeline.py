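"""End-to-end training convenience: labelled cases -> fitted codebook."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .codebook import Codebook, CodebookConfig, build_codebook
from .corpus import SUBSETS, TrainingCase
from .topics import TopicModel, fit_lda

__all__ = ["fit_subset_models", "train"]


def fit_subset_models(
    cases: Sequence[TrainingCase],
    K: int = 10,
    alpha: float = 0.1,
    beta: float = 0.01,
    n_iter: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
) -> dict[str, TopicModel]:
    """Fit one K-topic LDA model per subset of the labelled cases.

    Subset models get distinct derived seeds so their samplers are
    independent yet reproducible from the single ``seed``.
    """
    models: dict[str, TopicModel] = {}
    for si, s in enumerate(SUBSETS):
        docs = [list(c.document.tokens) for c in cases if c.subset == s]
        if not docs:
            raise ValueError(f"no training cases in subset {s!r}")
        models[s] = fit_lda(
            docs, K=K, alpha=alpha, beta=beta, n_iter=n_iter,
            burn_in=burn_in, seed=(seed * 4 + si) & 0x7FFFFFFF,
        )
    return models


def train(
    cases: Sequence[TrainingCase],
    risk_lexicon: Iterable[str] = (),
    titles: Mapping[str, Mapping[int, str]] | None = None,
    K: int = 10,
    alpha: float = 0.1,
    beta: float = 0.01,
    n_iter: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
    codebook_config: CodebookConfig = CodebookConfig(),
) -> Codebook:
    """Fit the four subset topic models and build the scored codebook."""
    models = fit_subset_models(
        cases, K=K, alpha=alpha, beta=beta, n_iter=n_iter,
        burn_in=burn_in, seed=seed,
    )
    return build_codebook(
        models,
        cases,
        risk_lexicon=risk_lexicon,
        titles=titles,
        config=codebook_config,
        meta={
            "seed": seed,
            "lda": {"K": K, "alpha": alpha, "beta": beta,
                    "n_iter": n_iter, "burn_in": burn_in},
        },
    )
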