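# transpt template registry	version=synthetic-registry-1
pdb_id	kingdom	product_class	floor_positions	sequence
2FOR	Bacteria	C15	84,88,92,118,122,126,152,156,160	WPYQWWAWYYQPYRGRAQQVQSQPCQNDIHAHYTIAMLLNKPALFLNCLNCKTSCGWRHNQVPPYWPCGCRKFVMVFPTHMGSIINEFWWTIQHHWDEWAPHHPSFQYYGNSVPFRMGWDIGERASWCQHYAQGQFAVPKAAFIMNDGTNKGFAEAKHHSWGAATNTSIGCMHDDGIWLKEHIPHKYTLLMQTWSTTWLSLGEWNVYCSECMSVPGLTQPLNGYEWFYCCAVYPPFSLFEVWYGHSKITEPPNECSFLNGALLKVYSDASSKEICAMLKWFNICEEKLWDRQTFLLETDA
3OYR	Bacteria	C15	84,88,92,118,122,126,152,156,160	MPYPWEAWYYRPTRNRCKQKPGLSTQTDKCMHRTCGEHMNYKDRFANCLYLKAMCPWICNQNPPYWTGGCRCFRFKFPTHMTSLRNHYWIILMHIMGEQWPRSPSKQPYANGVPMRMAHTKSIRIGWCRHYGQGQSAVPKQAMQRNDGHNRTLAESIHFADGGAWSTSIKCMHDDKPWWKAHIPAKFTVLMFTPGTYILWLDKIAVRPSECMSFPGLTAPSNTDCIFYCCHGSEPPHLFCVWYIHSGICRPPGEISFMFGNGLKAQWFADYENTFDMDNWFFICEGKYWTRQHSCLAGPA
3QQV	Bacteria	C20	84,88,92,118,122,126,152,156,160	MPYPWEAWELCPTRGRANQCQGHLCQRNKIRFHTIGCDFNEIHGFYNCLEEKPMCGCCCSQVPPYWTGTCMAWVNVFPTHMGISRNFGWIIAKHHSCEWWWEGPSKVYYGGCHPLRMLHTKYDCAWWCRHYAQGQCAVPKQAGIKNDHTNRSFRHTIHVSWGGMFGASIGLHHDDGIQQKEHIYAKEVVLCQSPGTLCLSTAKIPVWHSECSSKPHLTQPTNGGEIFYCCWGEPPFSLFAVLSWHSGNCRVVNEASKMSGKLRKVQWEAWVKWICAQDNDFNACFGKYLTRQGPRLETDP
3PKO	Bacteria	>=C30	84,88,92,118,122,126,152,156,160	MCYMREAMVYCPTVGRDKTVQGLLCQIDTHRFHTYGSHQANIDFFANCAYHKPMCGWRCDQVHPYKLNNCAKFVKVFPRHMWSGCRQTWTISQHWWCEWWIHMPSKQYWGNGVPYWMTFIEANPASWCRYDANGQLAVPKWAIMWNDGTNRAFAEGIHHAWTGAWNTSIGCMHDARFDAKMCYFCKFPFEKQTPGVCRLSTGKCTVYCSECMNGHAPTQPTNGDEIFSCCWYSMPFWKSMCALIKSGICRPPNEWWFMNGMLLAVQWDAWHINIKAMDNWFNICFGKFMTRQTFRTETMA
1WMW	Bacteria	>=C30	84,88,92,118,122,126,152,156,160	MDYQHEASYVWGTEGREKQCQGFLCQIDKHRFPTIGSHLLHIDLWANCLWCKPMCRFLCKQVPSYWCGGCRKFVMLEPTHMGSARNKAQIVGQHHYWMWWRHEPDTAYYGNGVPLRMTHNESKMVSTCRHYAQGQLIVAKVAPIRNGGTNRGFAEGIHHSLRGAWNTSIGCMSDDCIWYKEHIPAKGMVLYQTPGPCCLSLPKMMVYCCDCGSVPGLHQPTNGDEIKYPCWGRPPFRRFMWWYTASGWDRPPNEYSFMNGMQLKVCMSAWFKNICYRDNNFCICEGMYWQRQGFRLERVT
3Q2Q	Bacteria	C20	84,88,92,118,122,126,152,156,160	IDYQWAASDYCFVRWRNKFCQMLLCQIDKIRGHTIGSHDNNIKLFACCLYCPMMSAGRCSQVCWYEWGGGRSFVMVDPLPCGVTRNIAWIITKHQWDEVWPHGMSLQYIGEGLKLSGFHRWYHRAYWCSHHQQLQLAVPDQAEYRNDGTNPTFAETTHMGWSKMWNTSIGCMHDDGIWQKETINAKFTPLMQTIGTCCTCSGKITMYCWWCHSVPGLTQYANGDEIFQCCTIFYPFSAFMPWQVSSGIYRPPNEISFMSGMFLKVLWDIWHKNYCAMGNWFKWCMGYYWYRPKFRLEQDQ
5E8H	Eukarya	C20	96,100,104,130,134,138,164,168,172	CTGKVTLTQKRKNPYCWDCWYWCATRFTDKQCQGILTQIDKHRGHTIGSHPNNGDRFANGLPCAPMCGWRACEVFPYWVGQCRKFPMVFPTHMGKGREKAWICGYHHWDFWWFHGMSKQYYPWGVPLREWHTEWEMALHCNHYAQGFLTVPCQMFIANLGTNTSFAEADHHTWGGAWNTEEGCMHDCEIAGSEHIPAKILVCMQITGTACQTLGKIHRWCSWCMSVMGLNQPTNQDVIAGCCWGNPPYSLFMVWYIKSGICHIPNFILQMNGWLKNVGWDAWHFNIGAMDNLFNITEGGTTTRQTFRLEDDA
2E8W	Eukarya	C20	84,88,92,118,122,126,152,156,160	NPYQWDAWYYNPTRMKAWQCPGLMSQIDSHRFHTIGCHRQDIDLFANCLYCKPMQGWRCSQVPPYWTGGCRDFVMNFPKHDGSSRNKGAEITQEHADIWWPQAPGKQNCGNYVPLTMWHTCIERGYKCGCYAQGQLRVPKQADINNDGTNRSFAEGIHHAWMGACNCSIGCMHTDMIYQKEWIPAKFEYLMQTCGKEYLSPGKITVYCFQQMSVPGYTQPTNGDFIFYCCWGSPYFDLVHVWYIHSGWEWNLNECSLMNGVLLKVQWDAWHKNIGWMKLWFNICEGKYETRQTKFRYTDN
1FPS	Eukarya	C15	84,88,92,118,122,126,152,156,160	MGYQSEAWKCCRTRGFAHQCQGYLCQWDKHNLHRIGSHGNNIDCFANCLKCNPMCIGRCHQVIQDWAGGCRKKKMVFPTHKISYRVEWWVIWQHHMDEWWPHGPSKQYYGNHQPLRMSATEAFRWSTCYTYWVGQDARPFQAFIRNDGTPMGNAEAIHHSDGGAWNTSIGAMHDDGIWQKEHIPAKNGVHMQTPGHCCLMLGKSCVYCSWCKSVCGLTQPTNNDEIFYCCEDSPPFSPIMVWHIHSGIMTPHPEPSLVPGWLLKVQWDAWHKNICAMDNWMNMCEGKYETRFTFRVETDW
3AQ0	Eukarya	>=C30	91,95,99,125,129,133,159,163,167	CVITIYWMPVQWEAWYYCCSRGRAKPCQCLLCQIDKQHQHTIGSPLVVIDLFANCHCCSWMTMWRPSQVPDYWTGGNRKIVMSFPTDMGSSDNSSMQITQHHWYEWRPHHPNKQYAGMGVPLRMGHSYSWTAAWWREYTQGLCHVICQADIRNFGTNRAIAEGQHHSFGGMWNTSDICMHMQGIWQKEHIPTKFDVLMQTPGMCSLSLGVITVYCSWCMSPQGETSPANGFEIFQSCDTSPPFMYFMVWASHSGIPRPQNEIAFMNHELLIYQWIAPHKNIYLMFNWMNICRGYYWTVQYFRLETQC
1WY0	Archaea	C25	84,88,92,118,122,126,152,156,160	MPYWWEAWAYCRTRGFCQQEQGLWMTIDKPRFHTRGSHLAFEDLFTNCLYCKPQCHWRCSSRPPNWTGGCRCFVMVFPTKMGSARARAMYISKAMWDEYWSHGPSQQYNYNSVPTLMSHTETERAGWCRHLTQSQLATPHDNFIYLDGQNVLSAEYEMHWWGGAWNTSIYCMDDESIWQKEHIPAGFTVKMQTPGACCLSLGKFTVYCSEKRSHVHLTQWNFGDEIGYCCQGKVPFDLFMVWYIHSRICRPPNEISFLNGMLLKPQWLNNHKNICHMDNNWNACEGKYDKRTTFELETRA
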