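"""mitochar — comparative characterization of annotated vertebrate mitogenomes.

Composition/skew statistics, gene-layout (spacer/overlap) ledgers, codon
usage and RSCU under the vertebrate mitochondrial code, control-region and
OL motif/structure scanning, tRNA cloverleaf checking, 13-gene supermatrix
construction, and a synthetic-mitogenome generator with truth manifests.
"""

__version__ = "0.1.0"

from .mito_model import (  # noqa: F401
    GeneFeature,
    MitogenomeRecord,
    NameMap,
    read_feature_table,
    read_genbank_flatfile,
    validate_record,
    extract_region,
    revcomp,
)
from .composition import BaseCounts, SkewStats, count_bases, skew_stats  # noqa: F401
from .layout import build_ledger, summarize_ledger, gene_order_signature  # noqa: F401

from importlib import resources as _resources


def fixture_path(name: str):
    """Path to a packaged annotation fixture (see mitochar/fixtures/README.md).

    ``name`` is "ckumu" or "lmicroptera".
    """
    files = {
        "ckumu": "chelidonichthys_kumu_features.tsv",
        "lmicroptera": "lepidotrigla_microptera_features.tsv",
    }
    return _resources.files("mitochar.fixtures").joinpath(files[name])


FIXTURE_LENGTHS = {"ckumu": 16495, "lmicroptera": 16610}


def load_fixture(name: str) -> "MitogenomeRecord":
    """Load one of the two packaged coordinate-only fixture records."""
    return read_feature_table(
        str(fixture_path(name)),
        genome_length=FIXTURE_LENGTHS[name],
        record_id={"ckumu": "KY379222", "lmicroptera": "KY012348"}[name],
    )
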