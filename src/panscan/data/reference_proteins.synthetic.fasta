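>cdgA
GYDMVLSNVQTMNEPMWVPYFMINYERAVSHGFCTFWFCKITQCGEVMVHYNQWASGMHAHPQAAFQNRL
SIMRSFSMLETLFRKIWPWSCLAARGCPMFNNWFLIRAHYQAGWRFVEIFWMIYSIRAQIVGCIKFPADL
QSKKRDRYKCWSATFPHCRVSLWGQIPCSRWSCVYQGDANTHYNTPMFGGTFEIKHIWPCCWQIDSINPG
KWGEDICFQFTTHKDLSMSMKNYLCILQKHPMCIHCAGFTVTIQQLKKETRFVNNQTRQNTNSGVQCRSQ
YLECGLPFGCLRHFCRKSDNYPHGGDEFCAAPGYPAWLGYDQTAHCFDNKRSCQWPFGWSELCCHVGWPI
DWFFWASFHFHHQRTQSCPVTHDITKYFRIELKEMDNTPGEVLWQVTNPYGFEKKHTSYMPDQGNWDEDL
ARGWQDHPECHTPNLDGDHNGFYMYYKIRWVCEGLENGLDTPPQYTGNSEFFSISNDNNHEPQQRGSTQY
VENKVTYHNTVIASICNYVPCACGYQAGKHWFTTWACTNAKNGYFVMMHCTIWKFVFPCCNQWTSHTWIT
TFCYWCYFWGWSFAHEQKWWWPLEHMPLTCND
>cdgB
EHKKGTFQDHHKGNKTWFWWVHGSQMWHKNLLQEDKLWAQYDLRFQLLRARNLGEMTIDKEWEWAELFEY
HNVQWNMDLNVAWACAEMMCRAYCMMFPFFAWKESKRPHPCFKENGLNWTSEFLEFESEICECQYMAQEF
HGDHETFGGQGPHQIKMSFLGGGLMQMDMRRMHWKMIVREHDVLKAPLFDFTWSQLQDRTRYDMCHIKTS
PEDEAFSVNRTWVWANRGFPTVNTQAFYLKMFKGMWFHIKHWQIAFIAPGNWKVDQCHQFTICQDLNASS
KNYIMILQFSCMQIHLAGGYVTFTSGKYLTRFVNKVCRMITLRVIWCRFSPLKCGPPMGCLCHCARKSDN
YPHGGDEFAAAKKYPAWGGNDSCHHCEDVWESCQWPFHWMEMMAVLGRNIPWFVYYNFHHHLWMTMPCPV
TDSLIPNLCHYNSIPIMHHLNLMYPEKTVSATSWQFYYGI
>cdgC
RTPRPDNKSRDGGSGVLFAAALVLIFFAIILAIVILETRSRTREKTRTKKGVAIFAFLVVVALAAVAVIF
IIGKSTEKRPNPSDPTDFAAVAIAIFAFVVLFFLIIAVGGEKNNGPDDETPGSLVIILFVVLLVLAIIII
VAVIPPQDKEQRSNGRTRDFILFAFIFFVVIVIFLAALALKRDENRQDGNKRKSDVALLLLILLLIIAAA
IFIFFADDPQPKEGERTPPDTFAFIIFILAALIALAFIIIVLENSGDQPTDSRRKQQFIVIAAFVFAVFF
LLLLIVALSERSPRGSQRQSDPSIAAAVFVAVFIAVALVFALILTRPNKKGDNEEKPEEVVIVLIVLLFI
ALLFLLIIAVNERDRNREQPPNGSGFARSHQFAWHVTPICNWSTHWKWMFEGWWMCVYNILTRGVCGMQS
VNAHCGPIGAAPFANTLPGNAVMRHEPGKHLHHSTLLMQCVFLMGMAWRHSDEYWGVTEMRGNVQLIIVC
SDYIDHCQMDSILFCIWSDDECHQFGTWQMCNASGKNYIKELQEHQMCIHCRGQTVTLQQQVYLTRPVNN
YCSFDTKYYSWRRWIFGECGLPNGCLSHFARKSDNYPHGGDEFDAAYKHPAWWGEDGCAMCDDVDGSKGW
DFWWMELMYVLGRTIDWFMFTSFRAAAQMTMPCYVHEFIITQLTHKEWYFEMGQVDLHGTNPKGNSDKMT
SYMLHWYNWDENNYNGQQDHAHQHNPALDWDFFLLQMYYGYRGFSAGTENAYDTQPQYEVCQEFFSITNY
GNHEPQQTGHNQYVWLKPTYHNTGPASICIFPSCFCGYQAFFCDTCSWACCYWIWGPFLMMLYYIHKFVQ
PCCLQPGSCKWCCTQLCYMLKLVVNAIWGAKNHGV
>cdgD
RMVTFPPFLAMFICKGSYPSVKKCSDAFYFTFRMEEKMIEWLENQQLRVKITFKWQCLMRGWQIDSINPG
IVNVDICYQFKTHQDMNASYKNSIKGLQEAPMCSRCIGFTVTNQQINYLLRFVNPYCCFLDLEMSGCRSI
FIECGLPFYCACDKYRKSDNYIHGGDEFVIAPVSPRWWGERQCAHVFSVWASCNGPRGQMEKMYVLGRWI
RWFSWYSFHSHLQYYMHIPYMGVYYMKKVYEPEPPNNWTDQENPCSDPHHIWVRKRYKLNFGPTPFHESI
ANQPIKLETI
>cdgE
MWMFKTVECKHDGLNCFIQYDVMPDLKVWVCWVKSFKPMVKELILLQHVSHYDLRWIIHACHGAFRVWWR
LQDKTPYCGLGYACLCFVHHTAHPWYKHQMWYDMQDNIIHTPRSQFPYPTKHMAITVFHVAMTGPWCFHY
VHHNWANICMHWQIDPINPGKVSYDICYQFTTHFDAHASPKNYIKSLELHPMCWHCYFFTLTLQQLMRQR
REVNPYCICICKERSWCRSWFFKCGLPFGCWCPLARKSDNYSRGGDEFAAACKYMAWWTEDQGAHCFDKW
ESCQWPFGWYELSVYLGDTIGWFVWYSNDAMLQMWMDCPVLPVTFLRLMYHQGQFGEPYTNMNFSCTCPS
MENQVFQQMG
>cdgF
QGSREPDRGGSEEGDAAFAAIFFAIAFLVAVFVAIVQNDEQQTSEKRKKNTFAAAVIFFVIFLAVIALAV
LINKSSNGGKRESTSQNIFALVFFIVFFAAFLVVVVAFTQTQRSDPEKNPPPRIIIVAFAALLFFVLLIL
IIFLDTSDNNKTTDQRQPQFLFLIIALAVLAFAFFIFFVAQRSESRSKSKQQEKGAFIVIAAAVLIILAF
LIIIFLRQTDQKPREKENDGNVFLAVIIAVIFVLIILIFAIATRTRSDGRPKNRQDTFFAVAVVIAFILL
FLLAAIVVNPDNGQPNGPTTSQSLFALLFAFIIIAAAVLILAIFTQETRTSTPQKSPNKLFFIFALVFFI
AFLLFVAVFFPRPGNTQGSDDPRESWINPPEHRNHPMASPGWCFPICSYQRHHNHHNTRKSRDIMRNKFM
VMQKTGAEHLVKIMLCNCHPEGSWMMLAYLQFGILWPWGRVEPLYDPTLLPAHLFTFMHSNNWMNHGETY
EFFPLNNQIKSINPGEGSVDIMYNQTTHQQAMASVKNYIKELQLHTMHIHCTQNTVTLQQLKYLFRFWNP
YCYFCKLEMSWCRSIFLECGMKFKGLDHGARKSDNWPHGGDEFAAAPKYPAWWGEDYSARCFDVWESSQV
QFGALELSKVLGEWICALHIYSYHLHEPMKMPCPVMATQCLQFVCKKMWFKGGEVLLGVTHPLEFEDKHT
SYMDWQYGWDENLGPTWQDQPVCHRPNLDTMTAGLIAYRGYRGWCEKTENGYDTPEYYGVCNLFVKIMNY
NNHSPQQVGENWYVHVKPNYHNTPIESICIFEPCFCGYQAPFSITLDNECTYWKNDTLVMMHDYIQKVKQ
SCCFKHTMCTWICTERHFCQSVYEITFVLWCSVIW
>rmdA
DGGLSVTNQTILNTIGCQEYRLYNHPVMMCCHLAMRMDIMTHICSLTLWMFLAWFDWEDAPPMDLTVRVV
PWAQKHTKEQVCDGDFGWWHEHPYASRSMFCCMHYNAFANPGDPVRPYDFPISFTTEYCWVEWIHHGSIN
QVGSKKQTLSRTYKGEFSVKTVLMVTRWLKMYVQIHWNRFYMQCGYDLETMGVYIFHMKKHGQIDGCNPA
IWSHGICYQHTTHKDLADSVKNYIFILQLHPMCIHCAGFTVTWQQDKTLTRRLNNYCSFITLEMSFGTKI
WLECELPFMCLYLFARKSDRYEHGGDQFAAAPKFPSWMGEDGMEHCFMVWRSCYWPSRHPELMYALPRYI
DVKVWYAGHRHSCATMPCPVITGCMEVFTCFPKTMTYTGLEVLFHVTNSYPFEVKHICYQLWQGNYDENN
YRGWQDHPTCHRCNLSMDAIGLWNYYGYRGWCELLQNGYNTPPPYEFHQEFFSIQGYNNHEPQFVFSNQI
VTLKPTEHNTVIEKDCIFVPCFCAGQAGFHITLTWYCTYWKQDRFQHMHSFIQALEQPCCPQWEEVTWMD
TTPLFWVWVGVCFYYAFSLYRLYIRMRIHFNF
>rmdB
GPGSPKDQGPGTSGQAAIFLLVAAVLAIFAFFAFIIPDQSTDEPDSRPRGRALFALAFFFVAAFVALAAF
LFEEDSPEEKDTEPRTTFVVLLAAVILFFAIVFAAAAAKDQQDTSQPKGGNKNLLLIIAAALLLFLFAIA
FIVIRGERQNTRPPEKNRTALILVILFALVVVAAVLIILAKNPQGRRPSGQQQQPAIFAVAFAVALIIVV
LVLVFFQDRSPGPPDGPQESNCYRRAGISYSQWQNDWQHFMMVYMPAAGSYCMKAVGPSLHQIVDFCGWN
PFVACYCWQFKHWAWDSFHPNKWSVDIYYQFSGHQDLFAEVKNYLKAPQLTTMCIHCAQPTVREQQLKRL
PRFKNDYISFITLEMPWCITMMLECGLPFNCQVLFARKSDNHPHGGDQFAAAPWYPAWYGCDQQAHCFLH
WESCQWPFYRMELEDVLGTWIAWNVWYSDNVHLQVTMPCPVMGRMIFLVHLCRKSMNFTNKEVLLHVTNP
YLFKNKHYSWMEWQYIWDENNYRGWQIHPTTHRPNLTTHHMCHTMCHGYWGWCEGLTNGYDHPPQYTVCS
EFKSSTFYNNHEPQQVISGFYVALKPTYCNFVYESIEIFVPCFNGHQEGCHITYDWICRCYKQDEFVMMC
WLVSKFTQPCCWQWLSCTGTCYQPAMLWFKPLRGEIFSWFNHE
>hdgA
TKSQRSGDTESTTTKFALLIAAAAALAIAALVFFLLGDRQRESQQKQSETDFFAVFFAFFFAAFIVLFVI
FFRSSRDTGDDTSNTPEFILIAFFAVVIVIIFAAVLVAGTTNKNPGQNSEPDKFVVFAVIIAVFAFLAFL
VIVVGTTRDNGDTRDPSGEVFVAFIAIVAVIFALLFAAFLNEKTKNDQNNGEKKEIIIALAFVVVIFFFF
LAVIVVGPKKRQPDPTDQRDNAGVQQSLAIASALCLHQVESCVRTSNQFYRLHHWMHEAPPEVPLWRCVQ
SVPRCLPILCAAFCFRDMVMVTDCGNVPITDNLMMVRAYVHIDSGHSSWAPHLYRITKIWFVKAHQCFTV
ANPKVHGTLHPPGGQADHGPTNMWYCECDWEVYEQNNGHVEWCVTCLEYFAKAPVWYAECFGYPMWVLRQ
GSCTGMSPCQQIRPVDYRILCLRYEIMYAYNMYQDFQNVLFWFWIEFDSGTHTWRYTLCCPLKRAPPTDY
L
>hdgB
KTSSQNGSDDKQDNGVVAAFVILALAFAIFFLLFLISPPDQPENPEPGEKKAIAAAAAVLALVIAIVILL
AVTGPTNEGPKDPDRSKALILLVIFLIVLIIAVALAFFRNNEPKNPTEPNRRKAVFLFIAIILFVAAIVA
LAIAGDEDGKQKETTNGDQFLLLIVAVIVVFVLVIVVFLASRQGGDNSRQKEDTEIVAFFAVVFFVAFFF
ILIAIVDENRGDTPPGNQKKNVGMATCFSLNWAFFHDVAGIFIKYMCFTVDDILQRYHLIQVDGSAFTCS
REMVSGYNTDWNTCFREMVMVHDCGITPRTKMESRAKANVHHDFLFMGWAPHSYVLTPILFQAALSCEAV
ANPIHHGTLHEGKGDQDLGPTKMWYSEWDREVYRQNNGHVEWAVLCLMYIAFVGRWYAGIYASRWPELRQ
WLCHDESPMCCVKLVDMRKTHLGYEYMWAGSQYNDVQWVLFSCPVLPVNLHQQIRLSYLWLKFYIHIQTS
Y
>pcdgG
EKCISFQPMHIYSWYNTDTPVQNEHMWQPKQDGSDYFYMYCCLFYMIGQNHETSIDQWAYHWQIDITMPN
IWWTDICYEWTSHQQLNKEVKNYHKFDQLGPMCIHLAGFTVTLQQWKYLFRFQNNYCSFITLEMSWCRSI
KLENGLSFGASCQAARKSDNYPKGGDEFAAAPKWPAWDGEDRCGHCYDVQVSCAEPFAWMELRYSLMRWI
PVKNDYSFHPVNQQTMPCPEFDISHVMYCSHYNKAPSYLFFFQNWKLWHKSVVKWHKAMK
>bldD
ANSGHLASNEQDWYGPEFIRETSYVNTNQEETTMCSEIFYRHCHGKTFRENELRWDRHQRYFRITLMNPF
CQKIVAYCACIHLIMRWQPSIHKNGAHKAVGVYMERLSPINCQPFPLICHACNCHSRYARTWINILCTLG
RCSRVNHCYFYNGSLFPPDNTLWNQFA
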