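import textwrap

import pytest

TOY_GFF = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\ttest\tgene\t100\t400\t.\t+\t.\tID=g1
    chr1\ttest\tmRNA\t100\t400\t.\t+\t.\tID=t1;Parent=g1
    chr1\ttest\texon\t100\t200\t.\t+\t.\tID=t1.e1;Parent=t1
    chr1\ttest\texon\t301\t400\t.\t+\t.\tID=t1.e2;Parent=t1
    """
)

TOY_RMOUT = textwrap.dedent(
    """\
       SW  perc perc perc  query      position in query           matching       repeat              position in  repeat
    score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)   ID

     1000  12.5  0.0  0.0  chr1              1      100 (900)  +  L1-3            LINE/L1              1 100 (0)      1
      800  20.0  0.0  0.0  chr1            201      300 (700)  +  AluY            SINE/Alu             1 100 (0)      2
      600  25.0  0.0  0.0  chr1            401      450 (550)  +  Charlie1        DNA/hAT-Charlie      1  50 (0)      3 *
    """
)


@pytest.fixture
def toy_gff(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return path


@pytest.fixture
def toy_rmout(tmp_path):
    path = tmp_path / "toy.out"
    path.write_text(TOY_RMOUT)
    return path


@pytest.fixture
def toy_cvalue_table(tmp_path):
    path = tmp_path / "cvalues.tsv"
    path.write_text(
        "species\torder\tfamily\tc_value_pg\n"
        "Sp one\tOrdA\tFamA\t0.5\n"
        "Sp one\tOrdA\tFamA\t0.7\n"
        "Sp two\tOrdB\tFamB\t1.2\n"
    )
    return path
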