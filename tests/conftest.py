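import pytest

from leukotype.classify import load_classification_rules
from leukotype.models import (
    CaseProfile,
    Origin,
    Pathogenicity,
    Platform,
    RuleConfig,
    VariantCall,
)


@pytest.fixture(scope="session")
def cfg() -> RuleConfig:
    return RuleConfig(germline_gene_list=frozenset({"RUNX1", "TP53", "GATA2", "CEBPA"}))


@pytest.fixture(scope="session")
def rules():
    return load_classification_rules()


def make_variant(
    gene="NRAS",
    chrom="chr1",
    pos=114_713_909,
    ref="C",
    alt="T",
    origin=Origin.SOMATIC,
    pathogenicity=Pathogenicity.P,
    is_aml_driver=False,
    case_id="SJ000001",
    **vafs,
) -> VariantCall:
    """Variant factory; VAFs by keyword, e.g. wgs=0.06, wts='insufficient'."""
    return VariantCall(
        case_id=case_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        origin=origin,
        pathogenicity=pathogenicity,
        is_aml_driver=is_aml_driver,
        vaf_by_platform={Platform(k): v for k, v in vafs.items()},
    )


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def simple_case() -> CaseProfile:
    v = make_variant(wgs=0.35)
    return CaseProfile(case_id="SJ000001", blast_percent=63.0, variants=[v])
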