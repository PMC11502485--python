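import numpy as np
import pytest

from stratmr.harmonize import HarmonizedRecord, HarmonizedSet
from stratmr.sumstats import SummaryStatsTable, VariantAssociation


def make_assoc(
    vid="v1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-10,
    n=100_000,
):
    return VariantAssociation(
        variant_id=vid,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_record(
    vid="v1",
    bx=0.1,
    sx=0.005,
    by=0.02,
    sy=0.005,
    bz=0.05,
    sz=0.005,
    nx=100_000,
    ny=100_000,
    nz=100_000,
    ea="A",
    oa="G",
    eaf=0.3,
    px=1e-10,
):
    return HarmonizedRecord(
        variant_id=vid,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta_x=bx,
        se_x=sx,
        p_x=px,
        n_x=nx,
        beta_y=by,
        se_y=sy,
        n_y=ny,
        beta_z=bz,
        se_z=sz,
        n_z=nz,
    )


def make_hset(bx, by, sy, bz=None, sx=0.005, n=100_000):
    """Instrument set from parallel effect arrays (ids v1, v2, ...)."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    records = []
    for j in range(len(bx)):
        records.append(
            make_record(
                vid=f"v{j + 1}",
                bx=float(bx[j]),
                by=float(by[j]),
                sy=float(sy[j]),
                sx=sx,
                bz=None if bz is None else float(np.asarray(bz)[j]),
                sz=None if bz is None else 0.005,
                nz=None if bz is None else n,
                nx=n,
                ny=n,
            )
        )
    return HarmonizedSet(records=records)


def table_from_records(records, **kw):
    return SummaryStatsTable.from_records(records, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
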