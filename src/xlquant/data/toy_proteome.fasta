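>Rpb1 synthetic toy protein (1733 aa)
MNSIGKHWAHDRKLYQVQLGRNVRGTPEGSDLLIQRPVRTVETAKPGTGGNLAREFARLI
AKSHDSLKAPEIGYKNKDLLLDNIYKSQRFVLGSGPLNKVLFAMSKMRFPLGDIPDTNKK
PKPNTKPHDASQLDAKRQGITLRADGIHYAVGTQWTQFYDKGAAGMLWILVEDANYPKGD
DPTDSKIKAKNIQAAGLIPSHTHLADQALECEAVEFMGVAGEIQLSRSEKQHKDNEIRDL
YMPFSAVKRVTRQDMSEEFGPSAAVDGDQSCISGSSSLWLSNAQEDALTDKVRIKKFTDE
HRATTDSSEEEIIPTEHRDPSIYIWFMTFFGKKGPNLFLQPPDCLRRSPEAIKSLLVLVQ
VVHYLHILAMLDETKSPKKSTSHTGKRQEIHTYSAPTHFGTLEGSHGVDRELADGECAER
SDVNVGKQEVHKTAGHHFALHDTLVVKNRVVLINTGELEVAAWSLLESDTVGKVSLRHVF
MPSNTHCMSTLDGDTDAVVDCMFDVNLEKKPLRVEHETDSGVVVLSFLNGVDENFVKAAA
AIDGDTGGSPTEYYGLAYASDRIDLPHYVAELFGKPNKANLGVELGCYFNFFARTPTDLA
ETEYGPRGAPASLKVFHQKLMRFWLLALNGRAHDMSQNHIVWLVMQFRKRRSGWNLAFKE
APSVTPQDWTRNNTFYKPKMCKVDKIEIWENAEGILSGFQSPPIFGKKASFSQSGSTPVI
IAYQLGVSSTLVYSSPDSFVTNSGFALQVSLVYGTERVFYGLKITVLIYSSDTKGNGPKT
LGFLGSVSDDWHDDKNNADGPESHNNLALVDCSTRIQLACLLSQDDGDRSTTIKPLEMTH
VTDREVGTVELGLVAAAWGAHKSKDLNVSDGACVNTEHECKVARIKRPLGYYLVYYDWTP
LGVATDLGSNKQVKEFPLWIYSSYCGTMTHKLLSSHSWVPVGEAVIPCGTVTIVISGNDD
KPKQNKGLMPYSGEGKPKGVSKVQSGTSDKDQSAANEKKQQRIDGRLQAERLLKQKGMEV
LFVRILEGLNDKRSREPDNKEPLTAGVAPSCSSQAPQVDTVRKNTGGKLRTGWKPWKNGV
VQFFRVDTHHADEIEDKAVSVRDSQELSLEPNAKLVMVTAHAQRYSRVFPVAGLTEYDTP
GLHIAASIHIFRGDSKNHTDKTKVSQGHSWYAGDPSVAGKLRRVLPADDGACEGRKVSFY
LVVPVGFEVEVSPNASNPAVRDVQHADESPTRFYDPWTLHMRLPAQGVVYLFIEKTVSST
NLDDGSTPKKKAYLALKQSNVRRTVLTTSRSEEETLFKHIHDQKKSRQDGINGPSDTIDF
DSDYIIVENFEATHQTPWTVFHKPANQRNTATPHADGNRSYFALSDSLPEGFFPVVDRLA
SRGIHVPALKLQFGLLSASAGATGDQTMRPSAAANATRRNMEYKDPRRNKVDPTVFLDQN
SSISPLTQSAKISDVDEQSLDFNSTNGPESSYDCRTRLTVVVRRLFVTILSDLFGTFSRC
PGTYNPEPCFSLNPEFYNKRAVLSKATQSAVSPHYTCAEVVDLSRCDHTPHTESSGDAGT
LRKSLNENAISKTARASCMDERQTNPMPIIAQDYVTSQQGYNVVLILAFMNIKHPWSGGE
LDSELMRPDSNYSVDKKLASNTYFNIESMEDESAVQPEDTNKRFKVSKNNRRAAWLWSSQ
KVKKIGLDRKKTANDNGKNSSVTCATETLETADLEADYINSASQEQKYVMITY
>Rpb2 synthetic toy protein (1224 aa)
MRGPHTNVSTLCKVNNGLFKDSSELHFEESASVSKTPGLMARTPNLFSVNEEHPVRMLSK
NGDKKAEHWSDRKLRAQPGHRATVNLFETEVPTPVKNHAMEFATSGDNGSKTPYIYSIPS
GADELDALGLNYFAPFGSNNDVVSLKINTPYPDSGTAILSSREVEAISKAEVKRKDAWIA
MVTVPSEVPKSSDQAKGLIERCHECTAGDGFKKSIRNSYTGEVSSKGLVHDVDFLRREGD
GNQKLRQMAPEVTHAKTPLRTPPALEGTLFLGPRPTESKSCQSSEVQRAPPENWCRMEIQ
PGWLSFEDDKEAVSHYDAECHTIEAARSAKRLKGPVNPSSFVSTTEMAKPVNTVPPPGEV
ENEGKSVSSRMVRGPPLKLPKGCAEIHSVNNKGDNMRSLRVVHGISEEKETLSLIAADYA
SAGLVSLHVIVAMSPQGRTPGSFNQDYKMKYKIHKSSCKPAINKTDLHPIMSLHHMPETS
EWIEEEQGSRDIWFNPLSGKETFDDMPEDVRFNTVEFTDPNGLDPSDFSGVLTAQNYSTL
QYHSDNSVPGGFQADRIILALSVASYGMVPFDVQDAECSADSRFVKNLLGRALEIRVLHA
NKAAVKEECNADGTHRPGRSRRDLVFGLMKKLRETWSRPVQFKVTVHTRHLVTQEKTTLI
DSQDWTQDRIPRYYGHSWPPKISPSDPLFPYPKTNPGEGSKFMFTDDRTHLARSRKIKNF
EYFAGRQTLRSAGSRAAIPLPTGYKVWDAHKVEKWSSAKIDITGTPLWTPDKNPDVGDYT
NRFRQAAKIYRHGRSKPRQPYKRLGVKNFGDALQGERLDLGIEKYDGDSNYSLKSDPYKL
AHGDNSLCSKTKSKLNQSDVWFLYNGRTIDGTNDVAATNLECEAGEHPRKNTMACTKQYY
RANQRVGGDLDVGPGVAEKIIKGRWQEKTPLKTEMNGSKSLVANHLAPAASKNTVIIKQR
PRLRRELGQASMRQAPPHRVETMHRILVFMDIAYPGGTLIIEGKSPEQEDTGHGFQASGC
EPTSRYDPWSLLVEVAAFLGVTSEVRQMNEVRAKKYVTEDEDGYMEKNYKTGASQVLLYY
LSKILNLHPGAKEADDRQPQLVYARLAPGTDMQGEDYHYSGVTLRLQSAQPQLFDIVKEK
YDYMNGVSDVLDGSSLDERDIGHKSSSGNKPRLQVHACDWHGLINSFTNYGAGFLRRAVR
PLGGMAVSDSAVKLGLQSLRGIPD
>Rpb3 synthetic toy protein (318 aa)
MYVTVRVTSQPGKRSYGLAAQSPEPAQAHHQAESTPCSEQVTVARKLPTPYLKVTDVTFV
RQARQNSHCAVATQAQHNGLGSEKAPGWKKGVLISKTLGNKQTSDLRIGNKDPESIVTRK
LSGEITQTHQERTEVPFCEYQPVNQSSIEAAYYLELKIVLLTAVPSGDATDHLEALCSTS
TRQMGAAVNRDLHSDTVDREEKAIPKERLKEEYMLSFKVHYFRSTLVISVQPGWDAARDK
VLFVHLLPFLGMDSCFRLNQNEIYNRYLKSQCSPYMEGTKPETGHYRSDKSGMCLSSTHS
EPLGTRMDWTINDELLFP
>Rpb4 synthetic toy protein (221 aa)
MSDYWISKLCPSDMGPDKWQWGPFAKPMLVRVMSGSWGSLHVNPQNLHLDKVVLDLATSR
AVTIYIPFRILEGSGIVTTAANVQGSLNSGKASNNRENVVGDGFPSGETPVKTLLLTPLR
TMEKADRQHIKRSGAVDHSDPGKSHVSKDWTPTGGHANPKTCQSQTMNAFLEDTGKHRHG
KDVIMNMINEEVTKAVNRFPQYLGMDLLGGGTPASEANVIA
>Rpb5 synthetic toy protein (215 aa)
MEEMKPPDKSFSTCTVETIQKRNLQEKLAYVVTPDIRATTNRDTQEVGYPTFRRGAPGTT
YGLDTEKHYQEADRVHRIGILLKASEVKNVKSGAPPAMLANKVPALEKFNVNDLETSIQL
HAILKRTIPKFVALNADLRDKYETEKSKNLPKEDRTSPDMWSLASTLSLEDAKGKSDDDR
QFSVDHFVLNGESNSTEDFLDGIQGFQVTHATILD
>Rpb6 synthetic toy protein (155 aa)
MLGRAAYKSTFFMTWTQWGKDMDLIQTVESVSLTKQEQMRAAGKGGPTTRILEDFGVKLK
SPHDHFNPKMPLVVAKLDDLSTAISLEPRPFSAPEKCEHGVWHTDATLAGLLKCARLNDY
RFMATTSKWQQDSIKIFISTDEGESVIKTQKQSTD
>Rpb7 synthetic toy protein (171 aa)
MQIRRNSVVYHRRRATMDMAVSLYQPFEVTTGMYNKWVFGFANPGPYRCEGTDKSDCVPK
KSADGDLVSMNTLFTTHPVPAQLTISEYDTVKHSKRRSLLYNADVVVATRYTAWKDTDGD
PPPDHNVIFHKLKMWKYDQTVSIFKKIGDPFTAAKKTVGDGSVASVPIRGA
>Rpb8 synthetic toy protein (146 aa)
MAQEPPPVLVTDAADQIIWQVVGSGKGAGYVLCNVPNLTARRPTYVPNKTSTDRKSPKEA
FSASSKRTTVNVNRLTDVHTTLGLKETKMQRKCIPIFRADKGQSVLVNCTQDLTDIITSE
EDRTVGLLWKSGLITSKSIGAKIAVS
>Rpb9 synthetic toy protein (122 aa)
MNKGSAQSYFTKKKPMSEVEPQITLKTWSVLHENKIGERPTSTKKSGYEDRIAAQRGTSL
PTPVIKRVKLPVLVYICGSYKHFGRHTSSLLNSGQPAHSQFHQAVSATEGPNGLSKKRGR
IK
>Rpb10 synthetic toy protein (70 aa)
MGRTYNDQKVNTFKRYQAILCLVNPSEHQYSSHNLTHAAMSLKGVTPRPTTRINDRKVYL
ILFKIEKYIE
>Rpb11 synthetic toy protein (120 aa)
MKSDKLTTTKSTPDPNTFTQDTPTNDQRVASGGSRFTFKEPFFREGKEGPVLYFNIEPIC
QNYLVRPMQSSEGYAIDSVSDDYMRNFDANPKIVTQDDNQSNHDPLAKGTSEYFVYKDGA
>Rpb12 synthetic toy protein (70 aa)
MVTYRSFLKGGDKPMSVGTDKRVAPPVPETKWAWHYQAATVDEGHDKLIVHARCTATKSD
NYKARVRIEK
>TBP synthetic toy protein (240 aa)
MSYHHLFAQRPDNQPKPSGAIEVKKDYTFHKPSEQVTSSKGNYNKQLLMMQRYSSALELA
KQLEHSSDDRPRDTGSGLLHLAGKLQVPVGYDASSVVLAATVKTKASIKESKAPFKVAVR
AHEKSFDSTREKGKMVTVYNAELVEANHAYTIEAGRAHIPGANTQGAATAPVIRPVVRHS
TLRHNRGGYGSQRERTKPLFQGNKGKHTPPYDPVQLGYNFLACFRPWNKFPAKSNIVKPA
>TOA1 synthetic toy protein (286 aa)
MERKDTLHKILGSRHDNSIEAPRLPPSLWRLLHENHESVIDALAYHIGPFKGSPGTSFGL
ECNLGSGAEKQLPDQSGHGGPVTSNDVGAYIKVDDHQQKTHRQHGIVQSSYDWVAKESMV
IVEPLPVARVASQETGWTIRGFGATNKGIGALAHQQVFEFKHVPELPGLQAPRFQYCDAQ
LMQWVKPLDSQPLAACGHTGIEGDPQRHNVLEIGVDEKTLVMSNTSNNILHTVAARLHTD
LAVAVAAPNDAEGTKPNTFSDGNPSLVQRASDHVCDIDELAKGSGQ
>TOA2 synthetic toy protein (122 aa)
MQKVKVGQIKAEQKHCPVAAASEDVVEIRVFSYHKEMKNLLSNQKHALEYGHAKAVHDSS
EQAVNISLYFSGSDPCTALVGNNDTYDPFQARSELKYGDLVPGDGETERMVVKPPTTMEG
IS
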