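import pytest

from oudharmony.pipeline import run_pipeline
from oudharmony.synth import GeneratorConfig, generate_clean_bundle, inject_errors


@pytest.fixture(scope="session")
def clean_run():
    """Clean three-dialect bundle at 50 subjects/project plus pipeline output."""
    cfg = GeneratorConfig(n_subjects=50, seed=7)
    bundles, truth = generate_clean_bundle(cfg)
    db = run_pipeline(bundles, strict=True)
    return {"cfg": cfg, "bundles": bundles, "truth": truth, "db": db}


@pytest.fixture(scope="session")
def corrupted_run():
    """Corrupted bundle at default injection rates plus pipeline output."""
    cfg = GeneratorConfig(n_subjects=50, seed=11)
    clean, truth = generate_clean_bundle(cfg)
    corrupted, ledger = inject_errors(clean, cfg)
    db = run_pipeline(corrupted, strict=True)
    return {"cfg": cfg, "clean": clean, "corrupted": corrupted,
            "truth": truth, "ledger": ledger, "db": db}


@pytest.fixture(scope="session")
def small_clean():
    cfg = GeneratorConfig(n_subjects=8, seed=3)
    bundles, truth = generate_clean_bundle(cfg)
    return {"cfg": cfg, "bundles": bundles, "truth": truth}
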