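"""Versioned on-disk artifacts for a fitted pipeline.

An artifact directory holds:

- ``pipeline.json``  — featurizer configuration and all fitted
  vocabularies (term -> index, IDF tables, sentence model, layout);
- ``booster.json``   — the XGBoost ensemble (its own JSON format);
- ``model.json``     — classifier settings, selected hyperparameters,
  calibration parameters, cutoff and seed.

Version mismatches raise :class:`ArtifactVersionError` so callers can
distinguish them from bad input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .embeddings import EmbeddingTable
from .features import CountVocab, PrintedTfidf, TriageFeaturizer
from .model import PlattCalibrator, TriageClassifier
from .ppi import LogisticPathScorer
from .preprocess import SentenceBoundaryModel

ARTIFACT_VERSION = 1


class ArtifactVersionError(RuntimeError):
    pass


class _LoadedBooster:
    """Prediction-only wrapper around a deserialized XGBoost Booster."""

    def __init__(self, booster) -> None:
        self._booster = booster

    @classmethod
    def load(cls, path: str | Path) -> "_LoadedBooster":
        import xgboost as xgb
        raw = xgb.Booster()
        raw.load_model(str(path))
        return cls(raw)

    def predict_proba(self, X) -> np.ndarray:
        import xgboost as xgb
        p1 = self._booster.predict(xgb.DMatrix(X))
        return np.column_stack([1.0 - p1, p1])


def _tfidf_state(v: PrintedTfidf) -> dict:
    return {"max_terms": v.max_terms, "n_docs": v.n_docs_,
            "vocabulary": v.vocabulary_, "idf": v.idf_}


def _tfidf_from_state(state: dict) -> PrintedTfidf:
    v = PrintedTfidf(max_terms=state["max_terms"])
    v.vocabulary_ = dict(state["vocabulary"])
    v.idf_ = dict(state["idf"])
    v.n_docs_ = state["n_docs"]
    return v


def _count_state(v: CountVocab) -> dict:
    return {"vocabulary": v.vocabulary_}


def _count_from_state(state: dict) -> CountVocab:
    v = CountVocab()
    v.vocabulary_ = dict(state["vocabulary"])
    return v


_TFIDF_ATTRS = ("uni_vec_", "bi_vec_", "path_uni_vec_", "path_bi_vec_",
                "aug_uni_vec_", "aug_bi_vec_")
_COUNT_ATTRS = ("rel_uni_vec_", "rel_bi_vec_", "aug_rel_uni_vec_",
                "aug_rel_bi_vec_")


def save_pipeline(featurizer: TriageFeaturizer, classifier: TriageClassifier,
                  out_dir: str | Path, extra_config: Optional[dict] = None,
                  ) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not hasattr(featurizer, "uni_vec_"):
        raise ValueError("featurizer must be fitted before saving")

    emb_state = None
    if featurizer.embeddings_ is not None:
        t = featurizer.embeddings_
        emb_state = {"dim": t.dim,
                     "vectors": {w: t.vectors[w].tolist() for w in t.vectors}}
    scorer = featurizer.scorer_
    if not isinstance(scorer, LogisticPathScorer):
        raise ValueError("only the packaged logistic scorer is serializable; "
                         "re-register custom scorers via config at load time")
    pipeline = {
        "version": ARTIFACT_VERSION,
        "params": {
            "protein_terms": sorted(featurizer.protein_terms),
            "interaction_terms": sorted(featurizer.interaction_terms),
            "mutation_terms": sorted(featurizer.mutation_terms),
            "k_uni": featurizer.k_uni, "k_bi": featurizer.k_bi,
            "candidate_cap": featurizer.candidate_cap,
            "ci_min_len": featurizer.ci_min_len,
        },
        "scorer": {"intercept": scorer.intercept, "slope": scorer.slope,
                   "sentinel": scorer.sentinel},
        "sentence_model": {
            "abbreviations": sorted(featurizer.sentence_model_.abbreviations),
            "threshold": featurizer.sentence_model_.threshold,
            "min_count": featurizer.sentence_model_.min_count,
        },
        "n_docs": featurizer.n_docs_,
        "emb_df": featurizer.emb_df_,
        "embeddings": emb_state,
        "tfidf": {a: _tfidf_state(getattr(featurizer, a)) for a in _TFIDF_ATTRS},
        "counts": {a: _count_state(getattr(featurizer, a)) for a in _COUNT_ATTRS},
    }
    (out / "pipeline.json").write_text(json.dumps(pipeline), encoding="utf-8")

    classifier.booster_.get_booster().save_model(out / "booster.json")
    cal = classifier.calibrator_
    cal_state = None
    if cal is not None:
        if cal.lr_ is not None:
            cal_state = {"kind": "logistic",
                         "coef": float(cal.lr_.coef_[0, 0]),
                         "intercept": float(cal.lr_.intercept_[0])}
        else:
            cal_state = {"kind": "constant", "value": cal.constant_}
    model = {
        "version": ARTIFACT_VERSION,
        "cutoff": classifier.cutoff,
        "random_state": classifier.random_state,
        "cv": classifier.cv,
        "best_params": classifier.best_params_,
        "cv_average_precision": classifier.cv_average_precision_,
        "n_features": classifier.n_features_in_,
        "calibration": cal_state,
        "extra_config": extra_config or {},
    }
    (out / "model.json").write_text(json.dumps(model, indent=1),
                                    encoding="utf-8")
    return out


def load_pipeline(artifact_dir: str | Path,
                  ) -> tuple[TriageFeaturizer, TriageClassifier]:
    art = Path(artifact_dir)
    pipeline = json.loads((art / "pipeline.json").read_text(encoding="utf-8"))
    model = json.loads((art / "model.json").read_text(encoding="utf-8"))
    for blob, name in ((pipeline, "pipeline.json"), (model, "model.json")):
        if blob.get("version") != ARTIFACT_VERSION:
            raise ArtifactVersionError(
                f"{name}: artifact version {blob.get('version')} "
                f"!= supported {ARTIFACT_VERSION}")

    params = pipeline["params"]
    emb = None
    if pipeline["embeddings"] is not None:
        emb = EmbeddingTable({w: np.asarray(v) for w, v in
                              pipeline["embeddings"]["vectors"].items()})
    feat = TriageFeaturizer(
        protein_terms=params["protein_terms"],
        interaction_terms=params["interaction_terms"],
        mutation_terms=params["mutation_terms"],
        k_uni=params["k_uni"], k_bi=params["k_bi"],
        candidate_cap=params["candidate_cap"],
        ci_min_len=params["ci_min_len"],
        embeddings=emb,
        scorer=LogisticPathScorer(**pipeline["scorer"]),
        sentence_model=SentenceBoundaryModel(
            abbreviations=set(pipeline["sentence_model"]["abbreviations"]),
            threshold=pipeline["sentence_model"]["threshold"],
            min_count=pipeline["sentence_model"]["min_count"]),
    )
    # restore fitted state without re-fitting
    feat._prepare([])
    feat.n_docs_ = pipeline["n_docs"]
    feat.emb_df_ = dict(pipeline["emb_df"])
    for a in _TFIDF_ATTRS:
        setattr(feat, a, _tfidf_from_state(pipeline["tfidf"][a]))
    for a in _COUNT_ATTRS:
        setattr(feat, a, _count_from_state(pipeline["counts"][a]))
    feat.iw_tokens_ = {t.lower() for t in params["interaction_terms"]}
    feat.mu_tokens_ = {t.lower() for t in params["mutation_terms"]}
    feat._build_layout()

    clf = TriageClassifier(cutoff=model["cutoff"],
                           random_state=model["random_state"], cv=model["cv"])
    clf.best_params_ = model["best_params"]
    clf.cv_average_precision_ = model["cv_average_precision"]
    clf.n_features_in_ = model["n_features"]
    clf.classes_ = np.array([0, 1])
    clf.booster_ = _LoadedBooster.load(art / "booster.json")
    cal_state = model["calibration"]
    clf.calibrator_ = None
    if cal_state is not None:
        cal = PlattCalibrator()
        if cal_state["kind"] == "logistic":
            from sklearn.linear_model import LogisticRegression
            lr = LogisticRegression()
            lr.classes_ = np.array([0, 1])
            lr.coef_ = np.array([[cal_state["coef"]]])
            lr.intercept_ = np.array([cal_state["intercept"]])
            cal.lr_ = lr
        else:
            cal.constant_ = cal_state["value"]
        clf.calibrator_ = cal
    return feat, clf
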