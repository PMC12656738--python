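>synthetic_polA_reference synthetic stand-in for family-A DNA polymerase numbering; 928 aa, Phe at position 762
MRDEEYWIQVQNPVVDIHYILESDHKYHHWHIDRSPDGLTREKNEHNANTRPTEDCGPID
RVQRPWHPPDHLYDYCPHNYPDNLMQITQNKQLWFQVNCWHWWDICDNEYARLCKSREPG
KFLIDAPLWGWNCSDFVEFFLQFVANACMPYAAPPHLRFVVPRREAMFWCNTPLSLMDGW
TIGKSDDFPKIWDRFSHGFCIHHFRANLAIHQTGFPIYGSVDWIDIECESGMVSHRVKDF
LSIITSDLMAGGWCPDEIKRNFDGTAMADRQDISYFMNKQTCLWYCCRDVQIYFECFGKH
LHFVTLMSMGYWITPAQSMPLCSCDYQGCPWWKLMMMDTDQPRQRFPSWEYKWKHLQPQR
IYFQGLTSRVRPKLFHRPTQIWETVYSTRGAAAEKSLIPYPHRICSAPNSPPLMNEGHHQ
TPPVSQISFVWETDEARNYIGTVFYYGTAPVCPPGGTGIRQCSKAMHQNNLENHNLRCWQ
PNPPWWMKFLNETRWVRRWLSETRTAIEFNSYQMPTPRMSMKFNDWIQCGCSNRHERTCL
QWWALIIKHIQNLKPFTGPVWRNEDQIQEGKDYLWMSARCLENACSRLYWEDNVMCLPVF
NRPQLCFTDPEEHCASKYEFQRVYPELTQQYDDTTWPAFPWAPQFRMTLAGCMQSTRKFV
SDCINNDSMSMKVYIVIHGVNDADRDNKLGWLPPKREKPGKFFEYCNLRRLADYYAPNWK
VCSSDFSPNPHKMLFWGGRKSFHKPKTRNNHDCGWRSVSFFFSMMVEAPGWHRNRSNYRM
RLAPEVIWIKPACWIYWQPTDHQTKMFLCMVHEQEVNLSNQLVNHMCIPRPFYACENHRF
WHEENLWWKEGPGTLNSTHTEMDIEKNMPHRQFWVEMVATMHFYGIGNWVKYTQTFFTHP
CPHVVHMKWDPRWSGSFKYQDHPSSMLL
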